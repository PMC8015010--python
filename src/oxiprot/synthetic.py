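"""Synthetic 5+5 TMT experiment generator with known ground truth.

Emulates the structure of a quintuplicate control vs quintuplicate
irradiated TMT 10-plex experiment so that every pipeline stage can be
exercised and validated without any external data:

* random protein sequences with bacterial-like residue frequencies (so a
  tryptic/Lys-C digest yields realistic peptide lengths), always
  including one GAPDH-like protein whose digest contains the active-site
  peptide YAGQDIVSNASCTTNCLAPLAK with the canonical SCTTNC motif;
* per-peptide baseline abundances drawn log-normally, multiplicative
  per-channel loading biases, and log-normal reporter noise at a
  configurable coefficient of variation;
* background oxidative modifications sampled per class at rates matching
  the background fractions seen in unstressed bacteria (hydroxylation
  12.5%, dioxidation 2.1%, trioxidation 0.3%, carbonylation 0.6% of
  peptides), emitted as separate rows from the unmodified form of the
  same sequence;
* a 12% fraction of peptides with true fold changes, predominantly below
  2-fold (log2 fold ~ Normal(0, 0.35) truncated away from zero), plus
  explicitly planted large effects — by default the active-site peptide
  carrying trioxidation on the catalytic Cys at a true fold of 20.12;
* sampled co-isolation interference (a small fraction above the 30%
  filter threshold, to exercise it) and a low missing-channel rate.

What the generator does **not** emulate: peptide-level correlation
within proteins, intensity-dependent noise, isotope impurity
cross-talk between channels, retention-time effects, or search-engine
identification errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import NTERM, ModAnnotation, OXIDATIVE_CLASS_OF_MOD, peptide_monoisotopic_mass
from .digestion import ProteinRecord, digest
from .io import format_mods
from .quant import PeptideQuantRecord

__all__ = [
    "ACTIVE_SITE_PEPTIDE",
    "DEINO_ACTIVE_SITE_PEPTIDE",
    "PlantedEffect",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticConfigError",
    "generate_proteome",
    "generate_quant_table",
]

#: The E. coli GAPDH active-site tryptic peptide (contains SCTTNC; C12 is
#: the catalytic Cys within the peptide).
ACTIVE_SITE_PEPTIDE = "YAGQDIVSNASCTTNCLAPLAK"

#: A Deinococcus-type counterpart carrying the SCTTNS variant motif.
DEINO_ACTIVE_SITE_PEPTIDE = "YAGQDIVSNASCTTNSLAPLAK"

# Approximate E. coli proteome residue frequencies.
_RESIDUE_FREQS = {
    "A": 0.095, "C": 0.011, "D": 0.051, "E": 0.057, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.060, "K": 0.059, "L": 0.106,
    "M": 0.028, "N": 0.039, "P": 0.042, "Q": 0.044, "R": 0.055,
    "S": 0.058, "T": 0.054, "V": 0.071, "W": 0.014, "Y": 0.028,
}

_CLASS_TO_MOD = {v: k for k, v in OXIDATIVE_CLASS_OF_MOD.items()}


class SyntheticConfigError(ValueError):
    """Raised for inconsistent synthetic-data configuration."""


def _default_planted() -> tuple["PlantedEffect", ...]:
    return (
        PlantedEffect(
            peptide=ACTIVE_SITE_PEPTIDE,
            fold=20.12,
            mods=(
                ModAnnotation("trioxidation", (12,)),
                ModAnnotation("carbamidomethyl", (16,)),
                ModAnnotation("tmt", (22,)),
                ModAnnotation("tmt", (NTERM,)),
            ),
        ),
    )


@dataclass(frozen=True)
class PlantedEffect:
    """An explicitly planted peptide form with a known true fold change."""

    peptide: str
    fold: float
    mods: tuple[ModAnnotation, ...] = ()
    coisolation: float = 5.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_proteins: int = 40
    n_peptides: int = 500
    protein_length_mean: int = 300
    protein_length_sd: int = 80
    #: log-normal baseline abundance: ln-scale mean and sd
    baseline_log_mean: float = float(np.log(1e5))
    baseline_log_sd: float = 1.0
    #: per-channel multiplicative loading factors; None draws them
    #: log-normally with the sigma below
    loading_factors: tuple[float, ...] | None = None
    loading_log_sd: float = 0.1
    #: reporter noise coefficient of variation (log-normal multiplicative)
    noise_cv: float = 0.10
    #: background modification probability per oxidative class
    background_mod_probs: dict = field(
        default_factory=lambda: {
            "hydroxylated": 0.125,
            "dioxidized": 0.021,
            "trioxidized": 0.003,
            "carbonylated": 0.006,
        }
    )
    #: fraction of peptide rows carrying a true (mostly small) effect
    effect_fraction: float = 0.12
    effect_log2_sd: float = 0.35
    effect_log2_min: float = 0.1
    planted_effects: tuple[PlantedEffect, ...] = field(default_factory=_default_planted)
    #: co-isolation: this fraction of rows draws above the 30% threshold
    coisolation_high_fraction: float = 0.05
    missingness_rate: float = 0.02
    min_peptide_length: int = 6
    max_peptide_length: int = 50
    include_deinococcus_like: bool = False
    n_channels: int = 10
    n_treated: int = 5

    def __post_init__(self) -> None:
        for name, p in self.background_mod_probs.items():
            if not 0 <= p <= 1:
                raise SyntheticConfigError(f"probability {name}={p} outside [0, 1]")
        for p in (self.effect_fraction, self.coisolation_high_fraction, self.missingness_rate):
            if not 0 <= p <= 1:
                raise SyntheticConfigError(f"probability {p} outside [0, 1]")
        if self.n_proteins < 1:
            raise SyntheticConfigError("n_proteins must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth: one row per emitted peptide row, joinable to the
    quant table by (peptide, accession, mods)."""

    table: pd.DataFrame  # peptide, accession, mods, true_fold, planted, class flags
    loading_factors: np.ndarray


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    letters = list(_RESIDUE_FREQS)
    probs = np.array(list(_RESIDUE_FREQS.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def _protein_length(config: SyntheticConfig, rng: np.random.Generator) -> int:
    return max(60, int(rng.normal(config.protein_length_mean, config.protein_length_sd)))


def _gapdh_like(config: SyntheticConfig, rng: np.random.Generator, insert: str) -> str:
    """Random protein embedding ``insert`` as a clean tryptic peptide,
    with no stray active-site motif in the flanks."""
    while True:
        left = _random_sequence(_protein_length(config, rng) // 2, rng)
        right = _random_sequence(_protein_length(config, rng) // 2, rng)
        seq = left + "K" + insert + "V" + right
        if seq.count("SCTTN") == 1:
            return seq


def generate_proteome(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate FASTA records and a matching abundance catalog.

    The first record is always GAPDH-like (contains the active-site
    peptide with the canonical SCTTNC motif); a Deinococcus-like SCTTNS
    protein is added when configured. Catalog molecular weights are the
    monoisotopic protein mass in kDa; copy numbers are log-normal.
    """
    records = [
        ProteinRecord(
            accession="SYNGAPA",
            description="SYNGAPA glyceraldehyde-3-phosphate dehydrogenase-like (synthetic)",
            sequence=_gapdh_like(config, rng, ACTIVE_SITE_PEPTIDE),
        )
    ]
    if config.include_deinococcus_like:
        records.append(
            ProteinRecord(
                accession="SYNDRGAP",
                description="SYNDRGAP Deinococcus-like GAPDH with SCTTNS variant (synthetic)",
                sequence=_gapdh_like(config, rng, DEINO_ACTIVE_SITE_PEPTIDE),
            )
        )
    i = 0
    while len(records) < config.n_proteins:
        i += 1
        seq = _random_sequence(_protein_length(config, rng), rng)
        records.append(
            ProteinRecord(
                accession=f"SYN{i:04d}",
                description=f"SYN{i:04d} synthetic protein {i}",
                sequence=seq,
            )
        )
    records = records[: config.n_proteins]
    copies = 10 ** rng.normal(2.4, 1.0, size=len(records))
    catalog = pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "copies_per_cell": copies,
            "mw_kda": [peptide_monoisotopic_mass(r.sequence) / 1000.0 for r in records],
        }
    )
    catalog["ram"] = np.log10(catalog["copies_per_cell"] * catalog["mw_kda"])
    return records, catalog


def _digest_unique_peptides(
    proteome: Sequence[ProteinRecord], config: SyntheticConfig
) -> dict[str, str]:
    """Fully-cleaved, length-filtered peptides unique to one protein."""
    seen: dict[str, str | None] = {}
    for protein in proteome:
        for dp in digest(
            protein,
            max_missed=0,
            min_length=config.min_peptide_length,
            max_length=config.max_peptide_length,
        ):
            if dp.sequence in seen and seen[dp.sequence] != protein.accession:
                seen[dp.sequence] = None  # shared; drop
            else:
                seen[dp.sequence] = protein.accession
    return {pep: acc for pep, acc in seen.items() if acc is not None}


def _eligible_sites(peptide: str, mod_name: str) -> list[int]:
    from .chem import default_registry

    allowed = default_registry()[mod_name].allowed_residues
    return [i + 1 for i, aa in enumerate(peptide) if aa in allowed]


def _draw_effect_fold(config: SyntheticConfig, rng: np.random.Generator) -> float:
    while True:
        d = rng.normal(0.0, config.effect_log2_sd)
        if abs(d) >= config.effect_log2_min:
            return float(2.0 ** d)


def generate_quant_table(
    config: SyntheticConfig,
    rng: np.random.Generator,
    proteome: Sequence[ProteinRecord] | None = None,
) -> tuple[list[PeptideQuantRecord], SyntheticTruth]:
    """Generate peptide quant records and their ground truth.

    Abundance of peptide i in channel c = baseline_i x true_fold_i (in
    treated channels) x loading_c x log-normal noise. Background-modified
    peptides appear as separate rows from their unmodified counterparts;
    planted effects override sampling and are kept complete (no missing
    channels) with low co-isolation. When ``proteome`` is given it is
    reused (useful for repeated noise re-draws over one peptide set);
    otherwise one is generated, growing ``n_proteins`` as needed to reach
    ``n_peptides`` digest peptides.
    """
    if proteome is None:
        cfg = config
        while True:
            proteome, _ = generate_proteome(cfg, rng)
            if len(_digest_unique_peptides(proteome, config)) >= config.n_peptides:
                break
            cfg = SyntheticConfig(
                **{**cfg.__dict__, "n_proteins": int(cfg.n_proteins * 1.5) + 5}
            )
    unique = _digest_unique_peptides(proteome, config)

    planted_seqs = {p.peptide for p in config.planted_effects}
    for p in config.planted_effects:
        if p.peptide not in unique:
            raise SyntheticConfigError(
                f"planted peptide {p.peptide!r} not found in the digest"
            )

    all_peps = sorted(unique)
    pool = [p for p in all_peps if p not in planted_seqs]
    n_sample = min(config.n_peptides - len(planted_seqs), len(pool))
    chosen = (
        [str(p) for p in rng.choice(pool, size=n_sample, replace=False)]
        if n_sample > 0
        else []
    )
    peptides = sorted(set(chosen) | planted_seqs)

    # Rows: unmodified form for every peptide, plus background-modified
    # forms and planted forms as separate rows.
    rows: list[dict] = []
    for pep in peptides:
        acc = unique[pep]
        rows.append({"peptide": pep, "accession": acc, "mods": (), "planted": False})
        for cls, prob in config.background_mod_probs.items():
            if rng.random() < prob:
                mod_name = _CLASS_TO_MOD[cls]
                sites = _eligible_sites(pep, mod_name)
                if not sites:
                    continue  # peptide lacks eligible residues for this class
                site = int(rng.choice(sites))
                rows.append(
                    {
                        "peptide": pep,
                        "accession": acc,
                        "mods": (ModAnnotation(mod_name, (site,)),),
                        "planted": False,
                    }
                )
    for planted in config.planted_effects:
        for ann in planted.mods:
            ann.validate(planted.peptide)
        rows.append(
            {
                "peptide": planted.peptide,
                "accession": unique[planted.peptide],
                "mods": tuple(planted.mods),
                "planted": True,
                "fold": planted.fold,
                "coisolation": planted.coisolation,
            }
        )

    n_rows = len(rows)
    n_ch = config.n_channels
    n_control = n_ch - config.n_treated

    # True folds.
    folds = np.ones(n_rows)
    for i, row in enumerate(rows):
        if row["planted"]:
            folds[i] = row["fold"]
        elif rng.random() < config.effect_fraction:
            folds[i] = _draw_effect_fold(config, rng)

    # Abundance matrix.
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n_rows)
    if config.loading_factors is not None:
        loading = np.asarray(config.loading_factors, dtype=float)
        if loading.shape != (n_ch,):
            raise SyntheticConfigError(f"loading_factors must have length {n_ch}")
    else:
        loading = rng.lognormal(0.0, config.loading_log_sd, size=n_ch)
    effect = np.ones((n_rows, n_ch))
    effect[:, n_control:] = folds[:, None]
    matrix = baseline[:, None] * effect * loading[None, :]
    if config.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
        matrix = matrix * rng.lognormal(0.0, sigma, size=matrix.shape)

    # Co-isolation interference and missingness.
    coiso = np.where(
        rng.random(n_rows) < config.coisolation_high_fraction,
        rng.uniform(30.0, 80.0, size=n_rows) + 0.1,
        rng.uniform(0.0, 30.0, size=n_rows),
    )
    coiso = np.clip(coiso, 0.0, 100.0)
    missing_row = rng.random(n_rows) < config.missingness_rate
    missing_channel = rng.integers(0, n_ch, size=n_rows)

    records: list[PeptideQuantRecord] = []
    truth_rows: list[dict] = []
    from .chem import classify_oxidative_state
    from .quant import DEFAULT_CHANNELS

    for i, row in enumerate(rows):
        abundances = matrix[i].copy()
        if row["planted"]:
            c = row["coisolation"]
        else:
            c = float(coiso[i])
            if missing_row[i]:
                abundances[missing_channel[i]] = np.nan
        records.append(
            PeptideQuantRecord(
                peptide=row["peptide"],
                accession=row["accession"],
                mods=row["mods"],
                coisolation_percent=float(c),
                abundances=tuple(abundances),
            )
        )
        flags = classify_oxidative_state(row["mods"])
        truth_rows.append(
            {
                "peptide": row["peptide"],
                "accession": row["accession"],
                "mods": format_mods(row["mods"]),
                "true_fold": float(folds[i]),
                "planted": bool(row["planted"]),
                **flags.as_dict(),
            }
        )
    truth = SyntheticTruth(table=pd.DataFrame(truth_rows), loading_factors=loading)
    return records, truth
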