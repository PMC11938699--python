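CID20849290
     RDKit          2D
3-(3-ethylcyclopentyl)propanoic acid C10H18O2, hand-encoded; see invqspr.datagen.worked_compound
 30 30  0  0  0  0  0  0  0  0999 V2000
    1.2760    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943    1.2135    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323    0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0323   -0.7500    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.3943   -1.2135    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3907    1.0037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5054    2.0074    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.6201    3.0111    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.3083    4.4783    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    6.0467    2.5476    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5241    0.5932    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -4.0159    0.4364    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.3907   -1.0037    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2158    2.5838    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0309    1.6933    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3442    2.2172    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3442   -2.2172    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5321   -0.7762    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.6933   -1.9635    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2158   -2.5838    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.3944   -0.1110    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9335    1.6567    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.5017    3.1221    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    4.5091    0.8927    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    7.1614    3.5513    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.6809    2.0850    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -2.5503   -0.9066    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -5.5076    0.2796    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -4.1726    1.9282    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -3.8591   -1.0554    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  1  5  1  0
  1  6  1  0
  6  7  1  0
  7  8  1  0
  8  9  2  0
  8 10  1  0
  3 11  1  0
 11 12  1  0
  1 13  1  0
  2 14  1  0
  2 15  1  0
  3 16  1  0
  4 17  1  0
  4 18  1  0
  5 19  1  0
  5 20  1  0
  6 21  1  0
  6 22  1  0
  7 23  1  0
  7 24  1  0
 10 25  1  0
 11 26  1  0
 11 27  1  0
 12 28  1  0
 12 29  1  0
 12 30  1  0
M  END
$$$$
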