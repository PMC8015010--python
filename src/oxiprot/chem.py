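"""Amino-acid and modification mass chemistry.

This module owns the modification registry used throughout the pipeline:
named monoisotopic mass shifts, the residues each modification is allowed
to sit on, and the static/dynamic role of each. The default registry holds
the six modifications relevant to radiation-induced protein oxidation
experiments with TMT labelling:

* carbamidomethyl (+57.021 Da on C) — iodoacetamide alkylation from sample
  prep; its *absence* on a Cys in favour of trioxidation signals that the
  thiol was already oxidized.
* oxidation / hydroxylation (+15.995 Da) — one oxygen added to a side
  chain; on Met this is methionine sulfoxide.
* carbonylation (+13.979 Da) — gain of O with loss of two H, the classic
  protein-carbonyl oxidation marker.
* dioxidation (+31.990 Da) — two oxygens. The same mass shift could also
  arise from peroxidation; the two chemistries are indistinguishable at
  this level and are carried under the single "dioxidation" label.
* trioxidation (+47.985 Da) — three oxygens; on Cys this is the
  irreversible sulfonic acid.
* tmt (+229.163 Da) — the isobaric label, static on Lys and peptide
  N-termini; participates in mass arithmetic but never in oxidative
  classification.

Also here: peptide monoisotopic mass arithmetic, oxidative-state
classification of annotated peptides, and scanning protein sequences for
the GAPDH active-site motif S-C-T-T-N-[C/S] (the first Cys is the
catalytic residue; the Ser variant is characteristic of the
Deinococcus–Thermus lineage).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Union

import yaml
from pyteomics import mass as _pmass

__all__ = [
    "NTERM",
    "STANDARD_RESIDUES",
    "WATER_MONO",
    "ELEMENT_MONO",
    "ModificationDef",
    "ModificationRegistry",
    "ModAnnotation",
    "OxidationClassFlags",
    "ActiveSiteHit",
    "UnknownModificationError",
    "InvalidSequenceError",
    "InvalidModificationSiteError",
    "default_registry",
    "composition_mass",
    "mod_delta_mass",
    "validate_modification_site",
    "peptide_monoisotopic_mass",
    "classify_oxidative_state",
    "scan_active_site_motif",
    "OXIDATIVE_CLASS_OF_MOD",
]

#: Token used for a peptide/protein N-terminus in modification sites and
#: allowed-residue sets (avoids 0-based/1-based ambiguity; all residue
#: positions in this package are 1-based).
NTERM = "nterm"

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic element masses in Da (CODATA/IUPAC). Isotope-labelled
#: elements are keyed with a mass-number prefix, e.g. "13C".
ELEMENT_MONO: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "13C": 13.0033548378,
    "N": 14.0030740048,
    "15N": 15.0001088984,
    "O": 15.9949146196,
    "S": 31.97207100,
}

WATER_MONO = 2 * ELEMENT_MONO["H"] + ELEMENT_MONO["O"]

#: Residue (not free amino acid) monoisotopic masses, from pyteomics.
RESIDUE_MONO: Mapping[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}

#: Tolerance for agreement between a registered delta mass and the mass
#: recomputed from its elemental composition.
COMPOSITION_TOL_DA = 5e-4

#: Map from modification name to the oxidative class flag it sets.
#: Non-oxidative modifications (carbamidomethyl, tmt) are deliberately
#: absent and never contribute to classification.
OXIDATIVE_CLASS_OF_MOD: Mapping[str, str] = {
    "carbonylation": "carbonylated",
    "oxidation": "hydroxylated",
    "dioxidation": "dioxidized",
    "trioxidation": "trioxidized",
}


class UnknownModificationError(KeyError):
    """Raised when a modification name is not in the registry."""


class InvalidSequenceError(ValueError):
    """Raised for peptide/protein sequences with non-standard residues."""


class InvalidModificationSiteError(ValueError):
    """Raised when a modification is annotated on a disallowed residue."""


def composition_mass(composition: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition.

    Keys are element symbols, optionally isotope-prefixed ("13C", "15N");
    counts may be negative (e.g. carbonylation is +O −2H).
    """
    total = 0.0
    for element, count in composition.items():
        try:
            total += ELEMENT_MONO[element] * count
        except KeyError:
            raise KeyError(f"unknown element in composition: {element!r}") from None
    return total


@dataclass(frozen=True)
class ModificationDef:
    """A named monoisotopic mass shift with residue-specificity rules.

    Parameters
    ----------
    name:
        Unique identifier within a registry (e.g. ``"trioxidation"``).
    delta_mass:
        Monoisotopic mass shift in Da, stored at full precision.
    allowed_residues:
        One-letter residue codes (plus optionally :data:`NTERM`) the
        modification may sit on. Non-empty.
    role:
        ``"dynamic"`` (variable, searched) or ``"static"`` (applied
        everywhere, like the TMT tag).
    composition:
        Elemental formula as element → count; may be empty when only the
        delta mass is known. When present it must agree with
        ``delta_mass`` to within 5e-4 Da.
    """

    name: str
    delta_mass: float
    allowed_residues: frozenset[str]
    role: str = "dynamic"
    composition: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.allowed_residues:
            raise ValueError(f"modification {self.name!r}: allowed_residues is empty")
        if self.role not in ("dynamic", "static"):
            raise ValueError(f"modification {self.name!r}: role must be dynamic or static")
        bad = set(self.allowed_residues) - STANDARD_RESIDUES - {NTERM}
        if bad:
            raise ValueError(f"modification {self.name!r}: invalid residues {sorted(bad)}")
        if self.composition:
            derived = composition_mass(self.composition)
            if abs(derived - self.delta_mass) >= COMPOSITION_TOL_DA:
                raise ValueError(
                    f"modification {self.name!r}: composition mass {derived:.5f} "
                    f"disagrees with delta_mass {self.delta_mass:.5f}"
                )

    def allows(self, residue: str) -> bool:
        """True iff ``residue`` (one-letter code or the N-terminus token)
        is a permitted site for this modification."""
        return residue in self.allowed_residues


class ModificationRegistry:
    """Collection of :class:`ModificationDef` with unique names."""

    def __init__(self, mods: Iterable[ModificationDef] = ()) -> None:
        self._mods: dict[str, ModificationDef] = {}
        for mod in mods:
            self.register(mod)

    def register(self, mod: ModificationDef) -> None:
        if mod.name in self._mods:
            raise ValueError(f"duplicate modification name: {mod.name!r}")
        self._mods[mod.name] = mod

    def __getitem__(self, name: str) -> ModificationDef:
        try:
            return self._mods[name]
        except KeyError:
            raise UnknownModificationError(
                f"unknown modification: {name!r}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def __iter__(self):
        return iter(self._mods.values())

    def __len__(self) -> int:
        return len(self._mods)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._mods)

    def delta_mass(self, name: str) -> float:
        return self[name].delta_mass

    # -- YAML serialization ------------------------------------------------

    def to_yaml(self, path) -> None:
        data = [
            {
                "name": m.name,
                "delta_mass": m.delta_mass,
                "residues": "".join(sorted(r for r in m.allowed_residues if r != NTERM))
                + (f",{NTERM}" if NTERM in m.allowed_residues else ""),
                "role": m.role,
                "composition": dict(m.composition),
            }
            for m in self
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, source) -> "ModificationRegistry":
        """Load a registry from a YAML file path or open file object."""
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        mods = []
        for entry in data:
            residues: set[str] = set()
            spec = entry["residues"]
            for part in spec.split(","):
                if part == NTERM:
                    residues.add(NTERM)
                else:
                    residues.update(part)
            mods.append(
                ModificationDef(
                    name=entry["name"],
                    delta_mass=float(entry["delta_mass"]),
                    allowed_residues=frozenset(residues),
                    role=entry.get("role", "dynamic"),
                    composition=entry.get("composition") or {},
                )
            )
        return cls(mods)


def default_registry() -> ModificationRegistry:
    """The registry shipped with the package (six modifications)."""
    with resources.files("oxiprot.data").joinpath("modifications.yaml").open() as fh:
        return ModificationRegistry.from_yaml(fh)


_DEFAULT: ModificationRegistry | None = None


def _registry(registry: ModificationRegistry | None) -> ModificationRegistry:
    global _DEFAULT
    if registry is not None:
        return registry
    if _DEFAULT is None:
        _DEFAULT = default_registry()
    return _DEFAULT


Site = Union[int, str]


@dataclass(frozen=True)
class ModAnnotation:
    """One modification observed on a peptide.

    ``sites`` holds candidate positions: a single resolved 1-based
    position within the peptide (or :data:`NTERM`), or several candidates
    when site localization was ambiguous (reported in tables as e.g.
    "H/P"). At least one candidate is required.
    """

    mod_name: str
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("ModAnnotation requires at least one candidate site")
        for s in self.sites:
            if not (s == NTERM or (isinstance(s, int) and s >= 1)):
                raise ValueError(f"invalid site {s!r}: need 1-based position or {NTERM!r}")

    @property
    def is_ambiguous(self) -> bool:
        return len(self.sites) > 1

    @property
    def resolved_site(self) -> Site | None:
        """The single site when localized, else ``None``."""
        return self.sites[0] if len(self.sites) == 1 else None

    def validate(self, sequence: str, registry: ModificationRegistry | None = None) -> None:
        """Check every candidate site against the peptide and the
        modification's allowed residues; raises on violation."""
        reg = _registry(registry)
        mod = reg[self.mod_name]
        for s in self.sites:
            if s == NTERM:
                residue = NTERM
            else:
                if not 1 <= s <= len(sequence):
                    raise InvalidModificationSiteError(
                        f"{self.mod_name} site {s} outside peptide of length {len(sequence)}"
                    )
                residue = sequence[s - 1]
            if not mod.allows(residue):
                raise InvalidModificationSiteError(
                    f"{self.mod_name} not allowed on residue {residue!r} (site {s})"
                )


@dataclass(frozen=True)
class OxidationClassFlags:
    """Presence flags for the four oxidative modification classes.

    Flags record presence, not multiplicity; a peptide may carry several.
    """

    carbonylated: bool = False
    hydroxylated: bool = False
    dioxidized: bool = False
    trioxidized: bool = False

    @property
    def any_oxidative(self) -> bool:
        return self.carbonylated or self.hydroxylated or self.dioxidized or self.trioxidized

    def as_dict(self) -> dict[str, bool]:
        return {
            "carbonylated": self.carbonylated,
            "hydroxylated": self.hydroxylated,
            "dioxidized": self.dioxidized,
            "trioxidized": self.trioxidized,
        }


def mod_delta_mass(mod_name: str, registry: ModificationRegistry | None = None) -> float:
    """Monoisotopic delta mass (Da) of a registered modification.

    Raises :class:`UnknownModificationError` for unregistered names.
    """
    return _registry(registry).delta_mass(mod_name)


def validate_modification_site(
    mod_name: str, residue: str, registry: ModificationRegistry | None = None
) -> bool:
    """True iff ``residue`` (one-letter code or :data:`NTERM`) is an
    allowed site for the modification. Pure predicate."""
    return _registry(registry)[mod_name].allows(residue)


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InvalidSequenceError("empty peptide sequence")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise InvalidSequenceError(f"non-standard residues in sequence: {sorted(bad)}")


def peptide_monoisotopic_mass(
    sequence: str,
    mods: Iterable[ModAnnotation] = (),
    registry: ModificationRegistry | None = None,
) -> float:
    """Monoisotopic mass of a (modified) peptide in Da.

    mass = sum of residue masses + water + sum of modification deltas.
    Strictly additive in modifications; each annotation contributes its
    delta exactly once regardless of site ambiguity.
    """
    _validate_sequence(sequence)
    reg = _registry(registry)
    total = sum(RESIDUE_MONO[aa] for aa in sequence) + WATER_MONO
    for ann in mods:
        ann.validate(sequence, reg)
        total += reg.delta_mass(ann.mod_name)
    return total


def classify_oxidative_state(mods: Iterable[ModAnnotation]) -> OxidationClassFlags:
    """Derive oxidative class flags from a peptide's annotations.

    A flag is set iff at least one annotation of that class is present;
    carbamidomethyl and TMT annotations never set flags. Ambiguously
    localized sites still count — classification depends only on the
    modification class, not the residue.
    """
    flags = {v: False for v in OXIDATIVE_CLASS_OF_MOD.values()}
    for ann in mods:
        cls = OXIDATIVE_CLASS_OF_MOD.get(ann.mod_name)
        if cls is not None:
            flags[cls] = True
    return OxidationClassFlags(**flags)


@dataclass(frozen=True)
class ActiveSiteHit:
    """A GAPDH active-site motif match within a protein sequence.

    ``catalytic_cys_position`` is the 1-based protein coordinate of the
    motif's first Cys (= motif_start + 1).
    """

    protein_accession: str
    motif_start: int
    motif_sequence: str
    catalytic_cys_position: int
    variant: str  # canonical_SCTTNC | variant_SCTTNS

    def __post_init__(self) -> None:
        if not re.fullmatch(r"SCTTN[CS]", self.motif_sequence):
            raise ValueError(f"not an active-site motif: {self.motif_sequence!r}")
        if self.catalytic_cys_position != self.motif_start + 1:
            raise ValueError("catalytic Cys must be motif_start + 1")


_MOTIF_RE = re.compile(r"(?=(SCTTN[CS]))")


def scan_active_site_motif(
    protein_sequence: str, protein_accession: str = ""
) -> list[ActiveSiteHit]:
    """Find every (possibly overlapping) S-C-T-T-N-[C/S] motif match.

    The canonical SCTTNC motif carries the catalytic Cys at its second
    position; SCTTNS is the Deinococcus-type variant lacking the second
    Cys. Returns an empty list when the motif is absent.
    """
    _validate_sequence(protein_sequence)
    hits = []
    for m in _MOTIF_RE.finditer(protein_sequence):
        motif = m.group(1)
        start = m.start() + 1  # 1-based
        variant = "canonical_SCTTNC" if motif.endswith("C") else "variant_SCTTNS"
        hits.append(
            ActiveSiteHit(
                protein_accession=protein_accession,
                motif_start=start,
                motif_sequence=motif,
                catalytic_cys_position=start + 1,
                variant=variant,
            )
        )
    return hits
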