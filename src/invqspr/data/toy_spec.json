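{
 "seed_vertices": [
  0,
  1
 ],
 "seed_edges": [
  {
   "u": 0,
   "v": 1,
   "kind": "typical",
   "lengths": [
    1,
    4
   ],
   "mults": [
    1
   ],
   "path_fringes": null
  }
 ],
 "catalog": [
  {
   "element": "C",
   "hcount": 2,
   "children": []
  },
  {
   "element": "C",
   "hcount": 2,
   "children": [
    [
     1,
     {
      "element": "C",
      "hcount": 3,
      "children": []
     }
    ]
   ]
  },
  {
   "element": "C",
   "hcount": 2,
   "children": [
    [
     1,
     {
      "element": "C",
      "hcount": 2,
      "children": [
       [
        1,
        {
         "element": "C",
         "hcount": 3,
         "children": []
        }
       ]
      ]
     }
    ]
   ]
  },
  {
   "element": "C",
   "hcount": 2,
   "children": [
    [
     1,
     {
      "element": "C",
      "hcount": 0,
      "children": [
       [
        2,
        {
         "element": "O",
         "hcount": 0,
         "children": []
        }
       ],
       [
        1,
        {
         "element": "O",
         "hcount": 1,
         "children": []
        }
       ]
      ]
     }
    ]
   ]
  },
  {
   "element": "C",
   "hcount": 2,
   "children": [
    [
     1,
     {
      "element": "C",
      "hcount": 2,
      "children": [
       [
        1,
        {
         "element": "O",
         "hcount": 1,
         "children": []
        }
       ]
      ]
     }
    ]
   ]
  }
 ],
 "target_range": [
  -2.0,
  -1.5
 ],
 "rho": 2,
 "element_fix": {},
 "site_fringes": {},
 "n_range": [
  6,
  12
 ],
 "descriptor_bounds": {}
}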