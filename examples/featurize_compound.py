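"""Descriptor vector of a single molecule.

Builds the reference compound 3-(3-ethylcyclopentyl)propanoic acid,
decomposes it into interior and exterior at rho = 2, and prints its
graph-theoretic descriptors: counts of atoms, cycles, degrees, element and
configuration frequencies, and the average scaled atomic mass.
"""

from invqspr import featurize, worked_compound
from invqspr.twolayer import decompose

g = worked_compound()
d = decompose(g, rho=2)
print(f"molecule: {g.id}  ({g.n_heavy()} heavy atoms, {g.n_atoms()} total)")
print(f"interior: {sorted(d.interior)}")
print(f"exterior: {sorted(d.exterior)}")
print()
for name, value in featurize(g, rho=2).items():
    print(f"  {name:30s} {value}")
print()
print("The interior is the ring plus the first two chain carbons; the")
print("carboxyl group and the ethyl tail are exterior fringe trees.")
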