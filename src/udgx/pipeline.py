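"""End-to-end orchestration of the evolution, kinetics and structure stages.

These functions are the library behind the command-line interface: each
takes parsed inputs plus a :class:`PipelineConfig`, runs one analysis
end-to-end with stage-level logging (sequence counts into and out of every
filter), and returns a JSON-serialisable report; file output is written
only when an output directory is supplied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import coevolution as coev
from . import signatures as sig
from .conservation import percent_occurrence, profile_table
from .exceptions import InsufficientDataError, UdgxError
from .kinetics import (
    MichaelisMentenModel,
    fold_change,
    initial_rate,
)
from .msa import Msa, build_reference_map, read_alignment
from .structure import atom_distance, ca_rmsd, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_evolution_analysis",
    "run_kinetics_analysis",
    "run_structure_analysis",
]


#: fold-change comparisons of the mutant kinetics study:
#: (numerator enzyme, denominator enzyme, quantity)
DEFAULT_FOLD_COMPARISONS: tuple[tuple[str, str, str], ...] = (
    ("H109S/E52N", "H109S", "km"),
    ("H109S/R184A", "H109S", "km"),
    ("H109S", "H109S/E52N", "kcat"),
    ("H109S", "H109S/E52N", "efficiency"),
    ("H109S/Q53A", "H109S", "efficiency"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Constants of the analysis, defaulting to the published procedure.

    Conservation is called above 0.95 (strict), subfamilies split on the
    R107/H109 vs P107/N109 signatures, the co-occurrence query is Q at
    position 53, and kinetics uses [Et] = 200 nM with the Lineweaver–Burk
    fit.
    """

    ref_id: str = "MsmUdgX"
    udgx_signature: dict = field(default_factory=lambda: {107: "R", 109: "H"})
    family4_signature: dict = field(default_factory=lambda: {107: "P", 109: "N"})
    conservation_threshold: float = 0.95
    query_pos: int = 53
    query_residues: str = "Q"
    coevolution_metric: str = "mi"
    coevolution_positions: Optional[tuple[int, ...]] = None
    et: float = 200.0
    method: str = "lb"
    fold_comparisons: tuple[tuple[str, str, str], ...] = DEFAULT_FOLD_COMPARISONS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conservation_threshold <= 1.0:
            raise ValueError("conservation_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("udgx_signature", "family4_signature"):
            if key in raw:
                raw[key] = {int(p): r for p, r in raw[key].items()}
        if "fold_comparisons" in raw:
            raw["fold_comparisons"] = tuple(tuple(c) for c in raw["fold_comparisons"])
        if "coevolution_positions" in raw and raw["coevolution_positions"] is not None:
            raw["coevolution_positions"] = tuple(int(p) for p in raw["coevolution_positions"])
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["udgx_signature"] = {int(p): r for p, r in d["udgx_signature"].items()}
        d["family4_signature"] = {int(p): r for p, r in d["family4_signature"].items()}
        d["fold_comparisons"] = [list(c) for c in d["fold_comparisons"]]
        if d["coevolution_positions"] is not None:
            d["coevolution_positions"] = list(d["coevolution_positions"])
        return d


# ---------------------------------------------------------------------------
# evolution stage
# ---------------------------------------------------------------------------

def run_evolution_analysis(
    msa: Msa | str | Path,
    config: PipelineConfig = PipelineConfig(),
    outdir: Optional[str | Path] = None,
) -> dict:
    """Signature partition, conservation, uniqueness, co-occurrence, coevolution.

    Returns a report dict (config echoed under ``"config"``); with *outdir*
    set, also writes ``evolution_report.json``, per-group conservation and
    unique-position TSVs, the coevolution matrix TSV and the Newick tree.
    Stages degrade gracefully: an insufficient-data co-occurrence or a
    non-clusterable matrix is recorded in the report and the remaining
    stages still complete.
    """
    if not isinstance(msa, Msa):
        msa = read_alignment(msa)
    refmap = build_reference_map(msa, config.ref_id)
    logger.info("evolution: %d sequences, %d columns, %d reference positions",
                msa.n_sequences, msa.length, refmap.n_ref)

    udgx_sig = sig.SignatureSpec.from_dict(config.udgx_signature)
    fam4_sig = sig.SignatureSpec.from_dict(config.family4_signature)
    groups = sig.classify_subfamilies(msa, refmap, udgx_sig, fam4_sig)
    logger.info("partition: %d UdgX-type, %d family-4, %d unclassified",
                len(groups["udgx"]), len(groups["family4"]), len(groups["unclassified"]))

    report: dict = {
        "config": config.to_dict(),
        "n_sequences": msa.n_sequences,
        "n_columns": msa.length,
        "partition": {k: len(v) for k, v in groups.items()},
    }

    def conserved_for(ids: Sequence[str]) -> list[tuple[int, str, float]]:
        if len(ids) == 0:
            return []
        return sig.conserved_positions(msa.subset(ids), refmap, config.conservation_threshold)

    cons_udgx = conserved_for(groups["udgx"])
    cons_fam4 = conserved_for(groups["family4"])
    report["conserved_udgx"] = [
        {"refpos": p, "residue": r, "fraction": f} for p, r, f in cons_udgx
    ]
    report["conserved_family4"] = [
        {"refpos": p, "residue": r, "fraction": f} for p, r, f in cons_fam4
    ]

    if groups["udgx"] and groups["family4"]:
        uniq = sig.unique_conserved(
            msa.subset(groups["udgx"]), msa.subset(groups["family4"]),
            refmap, config.conservation_threshold,
        )
        report["unique_to_udgx"] = [
            {"refpos": p, "udgx_residue": a, "family4_consensus": b} for p, a, b in uniq
        ]
    else:
        logger.warning("unique-position stage skipped: a subfamily is empty")
        report["unique_to_udgx"] = None

    # percent occurrence of the query position, per subfamily and overall
    occ: dict[str, dict[str, float]] = {"all": percent_occurrence(msa, refmap, config.query_pos)}
    for name in ("udgx", "family4"):
        if groups[name]:
            occ[name] = percent_occurrence(msa.subset(groups[name]), refmap, config.query_pos)
    report["percent_occurrence"] = {"refpos": config.query_pos, "tables": occ}

    try:
        frac = sig.co_occurrence_fraction(
            msa, refmap, udgx_sig, config.query_pos, config.query_residues
        )
        report["co_occurrence"] = {
            "anchor": udgx_sig.to_dict(), "query_pos": config.query_pos,
            "query_residues": config.query_residues, "fraction": frac,
        }
    except InsufficientDataError as exc:
        logger.warning("co-occurrence stage: %s", exc)
        report["co_occurrence"] = {"error": str(exc)}

    positions = config.coevolution_positions or tuple(
        sorted({*udgx_sig.refpositions(), config.query_pos})
    )
    matrix = coev.coevolution_matrix(msa, refmap, positions, metric=config.coevolution_metric)
    report["coevolution"] = {
        "metric": matrix.metric,
        "positions": list(matrix.positions),
        "scores": matrix.scores.to_numpy().tolist(),
    }
    try:
        newick = coev.cluster_tree(matrix)
        report["coevolution"]["newick"] = newick
    except ValueError as exc:
        logger.warning("clustering stage: %s", exc)
        report["coevolution"]["newick"] = None
        report["coevolution"]["error"] = str(exc)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "evolution_report.json").write_text(json.dumps(report, indent=2) + "\n")
        profile_table(msa, refmap).to_csv(out / "conservation_all.tsv", sep="\t", index=False)
        for name in ("udgx", "family4"):
            if groups[name]:
                profile_table(msa.subset(groups[name]), refmap).to_csv(
                    out / f"conservation_{name}.tsv", sep="\t", index=False
                )
        matrix.scores.to_csv(out / f"coevolution_{matrix.metric}.tsv", sep="\t")
        if report["coevolution"]["newick"]:
            (out / "coevolution_tree.nwk").write_text(report["coevolution"]["newick"] + "\n")
    return report


# ---------------------------------------------------------------------------
# kinetics stage
# ---------------------------------------------------------------------------

def _rates_from_timecourses(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse (enzyme, S_nM, t_min, product_nM) rows to initial rates."""
    from .kinetics import TimeCourse

    rows = []
    for (enzyme, s), grp in df.groupby(["enzyme", "S_nM"], sort=False):
        g = grp.sort_values("t_min")
        try:
            est = initial_rate(TimeCourse(tuple(g["t_min"]), tuple(g["product_nM"]),
                                          substrate_nM=float(s)))
        except (InsufficientDataError, ValueError) as exc:
            logger.warning("time course %s @ %g nM skipped: %s", enzyme, s, exc)
            continue
        rows.append({"enzyme": enzyme, "S_nM": float(s), "v_nM_per_min": est.value})
    return pd.DataFrame(rows)


def _df_to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def run_kinetics_analysis(
    data: pd.DataFrame | str | Path,
    config: PipelineConfig = PipelineConfig(),
    outdir: Optional[str | Path] = None,
) -> dict:
    """Per-enzyme Michaelis–Menten fits plus configured fold-change rows.

    *data* is a long-format table: either rates (``enzyme, S_nM,
    v_nM_per_min``) or time courses (``enzyme, S_nM, t_min, product_nM``,
    collapsed to rates first).  Enzymes with fewer than 3 usable points are
    skipped with a warning.  Returns a report dict holding the parameter
    table (published layout) and the fold-change section; with *outdir*,
    writes CSV and markdown versions.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.read_csv(data)
    if data.empty:
        raise UdgxError("kinetics input is empty")
    if {"t_min", "product_nM"} <= set(data.columns):
        data = _rates_from_timecourses(data)
    missing = {"enzyme", "S_nM", "v_nM_per_min"} - set(data.columns)
    if missing:
        raise UdgxError(f"kinetics input lacks columns {sorted(missing)}")

    results = {}
    rows = []
    for enzyme, grp in data.groupby("enzyme", sort=False):
        if len(grp) < 3:
            logger.warning("enzyme %s: only %d points, skipped", enzyme, len(grp))
            continue
        try:
            res = MichaelisMentenModel.from_dataframe(grp, et=config.et).fit(config.method)
        except UdgxError as exc:
            logger.warning("enzyme %s: fit failed (%s), skipped", enzyme, exc)
            continue
        results[enzyme] = res
        rows.append(res.as_row(name=str(enzyme)))
    if not rows:
        raise UdgxError("no enzyme could be fitted")
    table = pd.DataFrame(rows)

    folds = []
    for a, b, quantity in config.fold_comparisons:
        if a in results and b in results:
            fc = fold_change(getattr(results[a], quantity), getattr(results[b], quantity))
            folds.append({
                "numerator": a, "denominator": b, "quantity": quantity,
                "ratio": round(fc.ratio, 2), "label": fc.label,
            })
    fold_table = pd.DataFrame(folds)

    report = {
        "config": config.to_dict(),
        "table": table.to_dict(orient="records"),
        "fold_changes": folds,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "kinetics_table.csv", index=False)
        md = ["# Kinetics parameters", "", _df_to_markdown(table), ""]
        if not fold_table.empty:
            md += ["# Fold changes", "", _df_to_markdown(fold_table), ""]
        (out / "kinetics_report.md").write_text("\n".join(md))
        (out / "kinetics_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


# ---------------------------------------------------------------------------
# structure stage
# ---------------------------------------------------------------------------

def run_structure_analysis(
    paths: Sequence[str | Path],
    distances: Sequence[tuple[str, str]] = (),
    rmsd_chain: Optional[str] = None,
    outdir: Optional[str | Path] = None,
) -> dict:
    """Named-atom distances on the first structure; C-alpha RMSDs vs the first.

    *distances* are pairs of ``chain:resnum:atomname`` selectors evaluated
    on ``paths[0]``; with *rmsd_chain*, every further structure is
    superposed onto the first over shared C-alphas of that chain.
    """
    if not paths:
        raise UdgxError("no structures given")
    structures = [read_structure(p) for p in paths]
    report: dict = {"files": [str(p) for p in paths], "distances": [], "rmsd": []}
    for sel_a, sel_b in distances:
        d = atom_distance(structures[0], sel_a, sel_b)
        report["distances"].append({"a": sel_a, "b": sel_b, "angstrom": round(d, 3)})
    if rmsd_chain is not None:
        for p, s in zip(paths[1:], structures[1:]):
            r = ca_rmsd(structures[0], s, rmsd_chain)
            report["rmsd"].append({
                "reference": str(paths[0]), "mobile": str(p),
                "chain": rmsd_chain, "rmsd_angstrom": round(r.rmsd, 3),
                "n_ca_pairs": r.n_pairs,
            })
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "structure_report.json").write_text(json.dumps(report, indent=2) + "\n")
        if report["distances"]:
            pd.DataFrame(report["distances"]).to_csv(
                out / "distances.tsv", sep="\t", index=False
            )
    return report
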