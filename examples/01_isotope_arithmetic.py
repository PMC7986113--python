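"""Convert delta-15N to atom % and back, and form atom percent excess.

Demonstrates the arithmetic underlying every tracer calculation: the
delta scale (per mil vs. atmospheric N2) maps one-to-one onto atom % 15N.
"""

from soilncycle.isotopes import (atom_percent_excess, atom_percent_to_delta,
                                 delta_to_atom_percent)

for delta in (-1000.0, 0.0, 5.0, 10_000.0):
    ap = delta_to_atom_percent(delta)
    print(f"delta {delta:>9.1f} permil  ->  {ap:.6f} atom% 15N"
          f"  ->  back to {atom_percent_to_delta(ap):.4f} permil")

# a fertilized soil at 1.37 atom% against a 0.3663 atom% natural background
ape = atom_percent_excess(1.37, 0.3663)
print(f"\natom percent excess of a labelled sample: {ape:.4f} atom%")
print("(the excess, not the raw atom%, carries the tracer signal)")
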