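"""Formula parsing, ion m/z and isotope-label arithmetic.

Computes the theoretical ion masses behind a caffeine metabolite study:
the unreported +O+2H caffeine metabolite, its d3 and 13C3 isotopologues,
and the deuterated hydroxybupropion that lost one label during
biotransformation.  Printed m/z values are what a high-resolution
instrument should observe for each ion, to within a few tenths of a ppm.
"""

from ebimet.chem import (
    CATION,
    M_PLUS_H,
    IsotopeLabelSpec,
    ion_mz,
    labeled_mz,
    parse_formula,
    ppm_error,
)

metabolite = parse_formula("C8H12N4O3")  # caffeine + O + 2H
print(f"caffeine +O+2H metabolite  [M+H]+  {ion_mz(metabolite, M_PLUS_H):.4f}")

d3 = IsotopeLabelSpec.parse("D:3")
c13 = IsotopeLabelSpec.parse("13C:3")
print(f"  d3 form                  [M+H]+  {labeled_mz(metabolite, M_PLUS_H, d3):.4f}")
print(f"  13C3 form                [M+H]+  {labeled_mz(metabolite, M_PLUS_H, c13):.4f}")

hydroxybupropion = parse_formula("C13H18ClNO2")
d9 = IsotopeLabelSpec.parse("D:9")
mz_d8 = labeled_mz(hydroxybupropion, M_PLUS_H, d9, labels_lost=1)
print(f"d8-hydroxybupropion        [M+H]+  {mz_d8:.4f}  (d9 precursor, 1 D lost)")

fragment = parse_formula("C9H11ClNO2")
print(f"ring-oxidation MS2 fragment  cation  {ion_mz(fragment, CATION):.4f}")

observed = 213.0981
theo = ion_mz(metabolite, M_PLUS_H)
print(f"\nobserved 213.0981 vs theory: {ppm_error(observed, theo):+.2f} ppm "
      "(inside the 3 ppm matching window)")
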