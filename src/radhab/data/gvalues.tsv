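# Default radiolytic yields (G-values) for gamma radiolysis of pure
# liquid water at ambient temperature, in molecules per 100 eV absorbed.
# Standard literature values for the primary water-splitting products;
# O2 is a secondary product (radical/peroxide recombination), so its
# primary yield is listed as 0.  Salinity and LET dependence are out of
# scope — supply your own table to override.
H2	0.45
H2O2	0.70
OH	2.70
e_aq	2.60
H	0.60
O2	0.0
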