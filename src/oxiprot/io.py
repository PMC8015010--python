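"""Tab-separated and YAML interchange formats.

Quant-table TSV schema (one row per peptide form): ``peptide``,
``accession``, ``mods``, ``coisolation``, then one abundance column per
channel label. The ``mods`` column is a semicolon-separated list of
``name@site`` items; sites are 1-based positions, the token ``nterm`` for
the peptide N-terminus, and ``/``-separated candidates for ambiguous
localization (e.g. ``oxidation@3/5``). Empty cells mean no value.

Results TSV appends the normalized abundances, fold change, raw and
BH-adjusted p-values, the fold-change category and the four oxidative
class flags; round-tripping a results file preserves categories, flags
and counts exactly.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .chem import NTERM, ModAnnotation, OxidationClassFlags
from .quant import PeptideQuantRecord, QuantConfig, QuantResult, TMTDesign

__all__ = [
    "format_mods",
    "parse_mods",
    "read_quant_table",
    "write_quant_table",
    "results_to_frame",
    "write_results",
    "read_results",
    "write_catalog",
    "load_config",
]

FLAG_COLUMNS = ("carbonylated", "hydroxylated", "dioxidized", "trioxidized")


def format_mods(mods: Sequence[ModAnnotation]) -> str:
    """Serialize annotations as ``name@site;name@site/site;...``."""
    return ";".join(
        f"{m.mod_name}@{'/'.join(str(s) for s in m.sites)}" for m in mods
    )


def parse_mods(text: str | float | None) -> tuple[ModAnnotation, ...]:
    """Inverse of :func:`format_mods`; blank/NaN means no modifications."""
    if text is None or (isinstance(text, float) and math.isnan(text)) or text == "":
        return ()
    mods = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        name, _, sitespec = item.partition("@")
        if not sitespec:
            raise ValueError(f"malformed modification {item!r}: expected name@site")
        sites = tuple(
            NTERM if s == NTERM else int(s) for s in sitespec.split("/")
        )
        mods.append(ModAnnotation(mod_name=name, sites=sites))
    return tuple(mods)


def read_quant_table(path, design: TMTDesign | None = None) -> list[PeptideQuantRecord]:
    """Read a peptide quant table TSV into records.

    Channel columns are taken from the design (default 10-plex layout).
    """
    design = design or TMTDesign()
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "accession": str})
    required = {"peptide", "accession"} | set(design.channel_labels)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    records = []
    for d in df.to_dict(orient="records"):
        coiso = d.get("coisolation")
        if coiso is not None and isinstance(coiso, float) and math.isnan(coiso):
            coiso = None
        records.append(
            PeptideQuantRecord(
                peptide=d["peptide"],
                accession=d["accession"],
                mods=parse_mods(d.get("mods")),
                coisolation_percent=coiso,
                abundances=tuple(float(d[c]) for c in design.channel_labels),
            )
        )
    return records


def write_quant_table(
    records: Iterable[PeptideQuantRecord], path, design: TMTDesign | None = None
) -> None:
    design = design or TMTDesign()
    rows = []
    for r in records:
        row = {
            "peptide": r.peptide,
            "accession": r.accession,
            "mods": format_mods(r.mods),
            "coisolation": r.coisolation_percent,
        }
        row.update(dict(zip(design.channel_labels, r.abundances)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def results_to_frame(results: Sequence[QuantResult], design: TMTDesign | None = None) -> pd.DataFrame:
    """Per-peptide results as a DataFrame (full internal precision)."""
    design = design or TMTDesign()
    rows = []
    for r in results:
        row = {
            "peptide": r.peptide,
            "accession": r.accession,
            "mods": format_mods(r.mods),
        }
        row.update(
            {f"norm_{c}": v for c, v in zip(design.channel_labels, r.normalized_abundances)}
        )
        row.update(
            {
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "adj_p_value": r.adj_p_value,
                "category": r.category,
            }
        )
        row.update(r.flags.as_dict())
        rows.append(row)
    columns = (
        ["peptide", "accession", "mods"]
        + [f"norm_{c}" for c in design.channel_labels]
        + ["fold_change", "p_value", "adj_p_value", "category"]
        + list(FLAG_COLUMNS)
    )
    return pd.DataFrame(rows, columns=columns)


def write_results(results: Sequence[QuantResult], path, design: TMTDesign | None = None) -> None:
    results_to_frame(results, design).to_csv(path, sep="\t", index=False)


def read_results(path, design: TMTDesign | None = None) -> list[QuantResult]:
    design = design or TMTDesign()
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "accession": str})
    out = []
    for d in df.to_dict(orient="records"):
        out.append(
            QuantResult(
                peptide=d["peptide"],
                accession=d["accession"],
                mods=parse_mods(d.get("mods")),
                normalized_abundances=tuple(
                    float(d[f"norm_{c}"]) for c in design.channel_labels
                ),
                fold_change=float(d["fold_change"]),
                p_value=float(d["p_value"]),
                adj_p_value=float(d["adj_p_value"]),
                category=str(d["category"]),
                flags=OxidationClassFlags(
                    **{f: bool(d[f]) for f in FLAG_COLUMNS}
                ),
            )
        )
    return out


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def load_config(path) -> tuple[QuantConfig, TMTDesign]:
    """Read pipeline configuration from YAML.

    Recognized keys: ``alpha``, ``coisolation_threshold``, ``t_test``
    (``student`` or ``welch``), and ``design`` as a mapping of channel
    label to group (``control``/``treated``). Missing keys fall back to
    defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    t_test = data.get("t_test", "student")
    if t_test not in ("student", "welch"):
        raise ValueError(f"t_test must be student or welch, got {t_test!r}")
    config = QuantConfig(
        alpha=float(data.get("alpha", 0.05)),
        coisolation_threshold=float(data.get("coisolation_threshold", 30.0)),
        equal_var=(t_test == "student"),
    )
    if "design" in data:
        assignment = {str(k): str(v) for k, v in data["design"].items()}
        design = TMTDesign(channel_labels=tuple(assignment), group_assignment=assignment)
    else:
        design = TMTDesign()
    return config, design
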