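"""Scan proteins for the GAPDH active-site motif and weigh the modified
active-site peptide.

The motif S-C-T-T-N-[C/S] marks the GAPDH catalytic Cys (the motif's
first Cys). Trioxidation of that Cys (+47.985 Da, cysteine sulfonic
acid) in place of the usual carbamidomethyl adduct is the signature of
irreversible oxidative inactivation.
"""

import numpy as np

from oxiprot import (
    ModAnnotation,
    NTERM,
    SyntheticConfig,
    generate_proteome,
    mod_delta_mass,
    peptide_monoisotopic_mass,
    scan_active_site_motif,
)

config = SyntheticConfig(n_proteins=10, include_deinococcus_like=True)
proteome, _ = generate_proteome(config, np.random.default_rng(3))

for record in proteome:
    for hit in scan_active_site_motif(record.sequence, record.accession):
        print(f"{hit.protein_accession}: {hit.motif_sequence} at {hit.motif_start}, "
              f"catalytic Cys at {hit.catalytic_cys_position} ({hit.variant})")

peptide = "YAGQDIVSNASCTTNCLAPLAK"
unmodified = peptide_monoisotopic_mass(peptide)
mods = [
    ModAnnotation("trioxidation", (12,)),      # catalytic Cys -> sulfonic acid
    ModAnnotation("carbamidomethyl", (16,)),   # second Cys alkylated as usual
    ModAnnotation("tmt", (22,)),
    ModAnnotation("tmt", (NTERM,)),
]
modified = peptide_monoisotopic_mass(peptide, mods)
print(f"\nactive-site peptide {peptide}")
print(f"unmodified monoisotopic mass: {unmodified:.5f} Da")
print(f"with trioxidation + carbamidomethyl + 2x TMT: {modified:.5f} Da "
      f"(shift {modified - unmodified:+.5f} Da)")
print(f"trioxidation alone contributes {mod_delta_mass('trioxidation'):+.3f} Da,")
print("the mass signature used to detect the sulfonic-acid conversion.")
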