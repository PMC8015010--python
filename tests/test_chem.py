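"""Modification chemistry: delta masses, site rules, classification,
peptide mass arithmetic and active-site motif scanning."""

import random
import re

import pytest

from oxiprot.chem import (
    NTERM,
    ActiveSiteHit,
    InvalidModificationSiteError,
    InvalidSequenceError,
    ModAnnotation,
    ModificationDef,
    ModificationRegistry,
    UnknownModificationError,
    classify_oxidative_state,
    composition_mass,
    mod_delta_mass,
    peptide_monoisotopic_mass,
    scan_active_site_motif,
    validate_modification_site,
)

O = 15.9949146196
H = 1.00782503207


@pytest.mark.parametrize(
    "name, printed, derived",
    [
        ("oxidation", 15.995, O),
        ("carbonylation", 13.979, O - 2 * H),
        ("dioxidation", 31.990, 2 * O),
        ("trioxidation", 47.985, 3 * O),
        ("carbamidomethyl", 57.021, 2 * 12.0 + 3 * H + 14.0030740048 + O),
        ("tmt", 229.163, None),
    ],
)
def test_delta_masses_match_composition_and_printed_values(registry, name, printed, derived):
    dm = mod_delta_mass(name, registry)
    assert round(dm, 3) == printed
    if derived is not None:
        assert dm == pytest.approx(derived, abs=1e-6)


def test_registry_composition_consistency_invariant(registry):
    for mod in registry:
        if mod.composition:
            assert abs(composition_mass(mod.composition) - mod.delta_mass) < 5e-4


def test_unknown_modification_names_the_identifier(registry):
    with pytest.raises(UnknownModificationError, match="glycation"):
        mod_delta_mass("glycation", registry)


def test_duplicate_names_rejected(registry):
    mod = ModificationDef("oxidation", O, frozenset("M"), composition={"O": 1})
    with pytest.raises(ValueError, match="duplicate"):
        ModificationRegistry([mod, mod])


def test_inconsistent_composition_rejected():
    with pytest.raises(ValueError, match="disagrees"):
        ModificationDef("bad", 10.0, frozenset("M"), composition={"O": 1})


def test_registry_yaml_round_trip(registry, tmp_path):
    path = tmp_path / "mods.yaml"
    registry.to_yaml(path)
    loaded = ModificationRegistry.from_yaml(path)
    assert loaded.names == registry.names
    for mod in registry:
        other = loaded[mod.name]
        assert other.delta_mass == pytest.approx(mod.delta_mass, abs=1e-9)
        assert other.allowed_residues == mod.allowed_residues
        assert other.role == mod.role


@pytest.mark.parametrize(
    "mod, residue, expected",
    [
        ("carbonylation", "M", False),  # Met is never searched for carbonyl
        ("trioxidation", "C", True),
        ("oxidation", "G", False),  # Gly is not searched for any oxidation
        ("carbonylation", "A", True),
        ("tmt", "K", True),
        ("tmt", NTERM, True),
        ("oxidation", NTERM, False),
    ],
)
def test_site_validity_follows_residue_specificity(registry, mod, residue, expected):
    assert validate_modification_site(mod, residue, registry) is expected


class TestPeptideMass:
    def test_single_glycine(self):
        assert peptide_monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_diglycine(self):
        assert peptide_monoisotopic_mass("GG") == pytest.approx(132.05349, abs=1e-4)

    def test_modification_additivity(self, registry):
        base = peptide_monoisotopic_mass("GM")
        ox = peptide_monoisotopic_mass("GM", [ModAnnotation("oxidation", (2,))])
        assert ox - base == pytest.approx(mod_delta_mass("oxidation", registry), abs=1e-9)

    def test_anagram_mass_equal(self):
        rng = random.Random(7)
        for _ in range(25):
            seq = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=12))
            perm = "".join(rng.sample(seq, len(seq)))
            assert peptide_monoisotopic_mass(seq) == pytest.approx(
                peptide_monoisotopic_mass(perm), abs=1e-9
            )

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(InvalidSequenceError):
            peptide_monoisotopic_mass("GXG")

    def test_mod_on_disallowed_residue_rejected(self):
        with pytest.raises(InvalidModificationSiteError):
            peptide_monoisotopic_mass("GAG", [ModAnnotation("oxidation", (1,))])

    def test_mod_site_outside_peptide_rejected(self):
        with pytest.raises(InvalidModificationSiteError):
            peptide_monoisotopic_mass("GM", [ModAnnotation("oxidation", (5,))])


class TestClassification:
    def test_trioxidized_active_site_annotation(self):
        # the published GapA row: trioxidation on C12 plus inert adducts
        mods = [
            ModAnnotation("trioxidation", (12,)),
            ModAnnotation("carbamidomethyl", (16,)),
            ModAnnotation("tmt", (22,)),
            ModAnnotation("tmt", (NTERM,)),
        ]
        flags = classify_oxidative_state(mods)
        assert flags.trioxidized
        assert not (flags.carbonylated or flags.hydroxylated or flags.dioxidized)

    def test_no_mods_no_flags(self):
        flags = classify_oxidative_state([])
        assert not flags.any_oxidative

    def test_class_is_presence_not_count(self):
        flags = classify_oxidative_state(
            [ModAnnotation("oxidation", (1,)), ModAnnotation("oxidation", (5,))]
        )
        assert flags.hydroxylated and not flags.dioxidized

    def test_carbamidomethyl_never_changes_classification(self):
        rng = random.Random(11)
        oxidative = ["oxidation", "carbonylation", "dioxidation", "trioxidation"]
        for _ in range(20):
            mods = [
                ModAnnotation(rng.choice(oxidative), (rng.randint(1, 9),))
                for _ in range(rng.randint(0, 3))
            ]
            with_cam = mods + [ModAnnotation("carbamidomethyl", (2,))]
            assert classify_oxidative_state(mods) == classify_oxidative_state(with_cam)

    def test_ambiguous_sites_still_classified(self):
        flags = classify_oxidative_state([ModAnnotation("oxidation", (3, 5))])
        assert flags.hydroxylated

    def test_annotation_requires_a_site(self):
        with pytest.raises(ValueError):
            ModAnnotation("oxidation", ())


class TestActiveSiteScan:
    def test_canonical_motif(self):
        hits = scan_active_site_motif("AAASCTTNCAAA", "P1")
        assert len(hits) == 1
        hit = hits[0]
        assert hit.motif_start == 4
        assert hit.catalytic_cys_position == 5
        assert hit.variant == "canonical_SCTTNC"
        assert hit.protein_accession == "P1"

    def test_serine_variant(self):
        (hit,) = scan_active_site_motif("AAASCTTNSAAA")
        assert hit.variant == "variant_SCTTNS"

    def test_absent_motif(self):
        assert scan_active_site_motif("AAAA") == []

    def test_overlapping_matches_found(self):
        hits = scan_active_site_motif("SCTTNSCTTNC")
        assert [(h.motif_start, h.variant) for h in hits] == [
            (1, "variant_SCTTNS"),
            (6, "canonical_SCTTNC"),
        ]

    def test_invalid_hit_construction_rejected(self):
        with pytest.raises(ValueError):
            ActiveSiteHit("P", 1, "SCTTNA", 2, "other")
        with pytest.raises(ValueError):
            ActiveSiteHit("P", 1, "SCTTNC", 5, "canonical_SCTTNC")

    def test_agrees_with_sliding_window_oracle(self):
        rng = random.Random(3)
        pattern = re.compile("SCTTN[CS]")
        # bias the alphabet so motifs actually occur
        alphabet = "SCTTN" * 3 + "AG"
        for _ in range(300):
            seq = "".join(rng.choices(alphabet, k=rng.randint(6, 60)))
            expected = [
                i + 1
                for i in range(len(seq) - 5)
                if pattern.fullmatch(seq[i : i + 6])
            ]
            assert [h.motif_start for h in scan_active_site_motif(seq)] == expected
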