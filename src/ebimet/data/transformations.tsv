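name	delta	phase
hydroxylation	+O	I
reduction	+H2	I
dehydrogenation	-H2	I
hydration	+H2O	I
oxidation-reduction	+OH2	I
dihydrodiol	+O2H2	I
methylation	+CH2	I
demethylation	-CH2	I
glucuronidation	+C6H8O6	II
sulfation	+SO3	II
acetylation	+C2H2O	II
glutathione-conjugation	+C10H15N3O6S	II
13C-isotopologue	+[13C]-C	adduct/isotope
sodium-adduct	+Na-H	adduct/isotope
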