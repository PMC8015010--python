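"""In-silico trypsin/Lys-C digestion and peptide-to-protein mapping.

Cleaves after every K (Lys-C is proline-insensitive) and after R unless
followed by P (trypsin rule), enumerating missed cleavages, then maps
observed peptide sequences back onto the proteome.
"""

from oxiprot import ProteinRecord, digest, map_peptides_to_proteins

protein = ProteinRecord("DEMO", "DEMO demo protein", "MKYAGQDIVSNAKRVLDKPGAR")

print("digest peptides (up to 2 missed cleavages):")
for d in digest(protein, max_missed=2, min_length=2):
    print(f"  {d.notation():<28} residues {d.start}-{d.end}, "
          f"{d.missed_cleavages} missed cleavage(s)")

proteome = [protein, ProteinRecord("OTHER", "OTHER", "AKYAGQDIVSNAK")]
mapping = map_peptides_to_proteins(["YAGQDIVSNAK", "VLDKPGAR", "NOTAPEPTIDE"], proteome)
print("\npeptide -> protein mapping:")
for pep, accs in mapping.mapping.items():
    print(f"  {pep} -> {sorted(accs)}")
print(f"unmapped: {mapping.unmapped}")
print(f"unique proteins hit: {mapping.n_unique_proteins}")
print("\nShared peptides map to every protein whose digest contains them;")
print("the unique-protein count is the union over all mapped peptides.")
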