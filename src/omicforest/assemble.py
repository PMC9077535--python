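"""Assembly of the protein x sample design matrix.

Each row corresponds to one (protein, sample) pair; the target is the
label-free proteomics intensity on the log2 scale.  Because one protein
maps to several transcripts, each transcript to several targeting miRNAs,
and each miRNA to several sponging circRNAs, multi-valued quantities are
collapsed with six summary statistics (mean, median, min, max, sum,
standard deviation) applied both to raw values and, for expression, to
their log2(x+1) transforms.

The default schema yields 196 raw feature columns:

====================================  =====
linear-transcript expression             12
miRNA expression (stringent + all)       24
transcript characteristics              36
protein characteristics                 48
MTI (miRNA-target-interaction) scores   12
sequencing depth                          1
circRNA sponging scores                   6
circRNA expression                       12
protein stability                       45
====================================  =====

miRNA linkage comes in two regimes: 'stringent' keeps only target
interactions with confidence score >= 80, 'all' keeps every interaction.
circRNAs are visible to a protein only through circRNA-miRNA links with
more than 7 binding sites.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import AA_ORDER, MultiomicsBundle

__all__ = [
    "STATS",
    "SummaryStats",
    "LinkageGraph",
    "DesignMatrix",
    "log2p",
    "summarize",
    "build_linkage",
    "assemble",
]

STATS = ("mean", "median", "min", "max", "sum", "sd")
STABILITY_STATS = ("mean", "median", "min", "max", "sum")
CATEGORICAL_COLUMNS = ("Organism", "Gene.encoded.by", "Version..sequence.")
TARGET = "log2_intensity"


def log2p(x):
    """log2(x + 1); defined for x >= 0 (TPM zeros map to 0)."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("log2p requires non-negative input")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    median: float
    min: float
    max: float
    sum: float
    sd: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.mean, self.median, self.min, self.max, self.sum, self.sd)


def summarize(values) -> SummaryStats:
    """Six-statistic summary of a group of linked values.

    Empty groups yield NaN for every statistic (the row is later removed by
    complete-case filtering); singleton groups have sd = 0 rather than NaN
    so that single-transcript proteins survive that filter.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        nan = float("nan")
        return SummaryStats(nan, nan, nan, nan, nan, nan)
    if not np.isfinite(arr).all():
        raise ValueError("summarize requires finite values")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(float(arr.mean()), float(np.median(arr)), float(arr.min()),
                        float(arr.max()), float(arr.sum()), sd)


def _stat_block(arr: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized six-statistic summary over axis 0 of a (k, S) array."""
    if arr.shape[0] == 1:
        sd = np.zeros(arr.shape[1])
    else:
        sd = np.std(arr, axis=0, ddof=1)
    return {
        "mean": arr.mean(axis=0), "median": np.median(arr, axis=0),
        "min": arr.min(axis=0), "max": arr.max(axis=0),
        "sum": arr.sum(axis=0), "sd": sd,
    }


@dataclass
class LinkageGraph:
    """protein -> transcript -> miRNA -> circRNA edges after thresholding.

    ``transcript_to_mirnas_*`` map to lists of (mirna_id, score) pairs;
    ``mirna_to_circs`` maps to lists of (circ_id, n_sites) with only the
    links above the binding-site cutoff retained.
    """

    protein_to_transcripts: dict[str, list[str]]
    transcript_to_mirnas_all: dict[str, list[tuple[str, float]]]
    transcript_to_mirnas_stringent: dict[str, list[tuple[str, float]]]
    mirna_to_circs: dict[str, list[tuple[str, int]]]
    stringent_cutoff: float = 80.0
    min_circ_sites: int = 7

    def protein_mirna_edges(self, protein: str, stringent: bool
                            ) -> list[tuple[str, str, float]]:
        """(transcript, mirna, score) edges over the protein's transcripts."""
        table = (self.transcript_to_mirnas_stringent if stringent
                 else self.transcript_to_mirnas_all)
        edges = []
        for tid in self.protein_to_transcripts.get(protein, []):
            edges.extend((tid, m, s) for m, s in table.get(tid, []))
        return edges

    def protein_mirnas(self, protein: str, stringent: bool) -> list[str]:
        """De-duplicated, sorted miRNA set targeting any of the protein's transcripts."""
        return sorted({m for _, m, _ in self.protein_mirna_edges(protein, stringent)})

    def protein_circ_links(self, protein: str) -> list[tuple[str, str, int]]:
        """(circ, mirna, n_sites) links reaching the protein via its ALL-regime miRNAs."""
        links = []
        for m in self.protein_mirnas(protein, stringent=False):
            links.extend((c, m, n) for c, n in self.mirna_to_circs.get(m, []))
        return links


def build_linkage(bundle: MultiomicsBundle, stringent_cutoff: float = 80.0,
                  min_circ_sites: int = 7) -> LinkageGraph:
    """Threshold the raw linkage tables into a LinkageGraph.

    A target interaction is 'stringent' when score >= ``stringent_cutoff``
    (the boundary is inclusive); a circRNA-miRNA link is retained only when
    n_sites > ``min_circ_sites`` (exclusive).  Edges referencing unknown
    entities are dropped with a warning.
    """
    known_tr = set(bundle.transcript_expr.index)
    known_mir = set(bundle.mirna_expr.index)
    known_circ = set(bundle.circ_expr.index)

    p2t: dict[str, list[str]] = {}
    for p, tid in bundle.protein_transcript_map.itertuples(index=False):
        if tid not in known_tr:
            warnings.warn(f"dropping mapping to unknown transcript {tid}")
            continue
        p2t.setdefault(p, []).append(tid)

    t2m_all: dict[str, list[tuple[str, float]]] = {}
    t2m_str: dict[str, list[tuple[str, float]]] = {}
    for m, tid, score in bundle.mti_table.itertuples(index=False):
        if tid not in known_tr or m not in known_mir:
            warnings.warn(f"dropping MTI edge with unknown id ({m}, {tid})")
            continue
        t2m_all.setdefault(tid, []).append((m, float(score)))
        if score >= stringent_cutoff:
            t2m_str.setdefault(tid, []).append((m, float(score)))

    m2c: dict[str, list[tuple[str, int]]] = {}
    for c, m, n_sites in bundle.circ_site_table.itertuples(index=False):
        if c not in known_circ or m not in known_mir:
            warnings.warn(f"dropping circRNA link with unknown id ({c}, {m})")
            continue
        if n_sites > min_circ_sites:
            m2c.setdefault(m, []).append((c, int(n_sites)))

    return LinkageGraph(p2t, t2m_all, t2m_str, m2c,
                        stringent_cutoff=stringent_cutoff,
                        min_circ_sites=min_circ_sites)


@dataclass
class DesignMatrix:
    """Feature table with a schema manifest.

    ``table`` is indexed by (protein_id, sample_id); ``manifest`` maps each
    feature column to its category; ``categorical`` lists columns kept as
    raw labels (dummy-encoded during preprocessing).
    """

    table: pd.DataFrame
    manifest: dict[str, str]
    categorical: list[str] = field(default_factory=list)
    target: str = TARGET

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.table.columns if c != self.target]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for col in self.feature_columns:
            cat = self.manifest.get(col, "feature")
            counts[cat] = counts.get(cat, 0) + 1
        return counts

    @classmethod
    def from_frame(cls, df: pd.DataFrame, categorical=(), target: str | None = None,
                   category: str = "feature") -> "DesignMatrix":
        manifest = {c: category for c in df.columns if c != target}
        return cls(table=df, manifest=manifest, categorical=list(categorical),
                   target=target if target is not None else TARGET)

    def write(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        path = Path(path)
        self.table.to_csv(path, sep="\t")
        if manifest_path is None:
            manifest_path = path.with_suffix(path.suffix + ".manifest.json")
        meta = {"target": self.target, "categorical": self.categorical,
                "columns": self.manifest}
        Path(manifest_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path: str | Path, manifest_path: str | Path | None = None
             ) -> "DesignMatrix":
        path = Path(path)
        if manifest_path is None:
            manifest_path = path.with_suffix(path.suffix + ".manifest.json")
        meta = json.loads(Path(manifest_path).read_text())
        table = pd.read_csv(path, sep="\t", index_col=[0, 1])
        for col in meta["categorical"]:
            table[col] = table[col].astype(str)
        return cls(table=table, manifest=meta["columns"],
                   categorical=meta["categorical"], target=meta["target"])


# ---------------------------------------------------------------------------
# per-block feature builders


def transcript_expression_features(protein: str, graph: LinkageGraph,
                                   bundle: MultiomicsBundle) -> pd.DataFrame:
    """12 columns: six summaries of TPM and of log2(TPM+1), per sample."""
    return _expression_block(bundle.transcript_expr,
                             graph.protein_to_transcripts.get(protein, []),
                             "mrna", bundle.samples)


def mirna_features(protein: str, graph: LinkageGraph, bundle: MultiomicsBundle
                   ) -> pd.DataFrame:
    """24 expression + 12 MTI-score columns across the two regimes."""
    blocks = []
    for regime in ("stringent", "all"):
        mirs = graph.protein_mirnas(protein, stringent=(regime == "stringent"))
        blocks.append(_expression_block(bundle.mirna_expr, mirs,
                                        f"mirna_{regime}", bundle.samples))
        scores = [s for _, _, s in
                  graph.protein_mirna_edges(protein, stringent=(regime == "stringent"))]
        stats = summarize(scores).as_tuple() if scores else (math.nan,) * 6
        blocks.append(pd.DataFrame(
            {f"mti_{regime}_{st}": v for st, v in zip(STATS, stats)},
            index=bundle.samples))
    return pd.concat(blocks, axis=1)


def circ_features(protein: str, graph: LinkageGraph, bundle: MultiomicsBundle
                  ) -> pd.DataFrame:
    """12 circRNA expression columns + 6 circ_score (binding sites) columns."""
    links = graph.protein_circ_links(protein)
    circ_ids = sorted({c for c, _, _ in links})
    out = _expression_block(bundle.circ_expr, circ_ids, "circ", bundle.samples)
    sites = [n for _, _, n in links]
    stats = summarize(sites).as_tuple() if sites else (math.nan,) * 6
    for st, v in zip(STATS, stats):
        out[f"circ_score_{st}"] = v
    return out


def _expression_block(expr: pd.DataFrame, ids: list[str], prefix: str,
                      samples: list[str]) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    if ids:
        arr = expr.loc[ids].to_numpy(dtype=float)
        raw = _stat_block(arr)
        logged = _stat_block(np.log2(arr + 1.0))
    else:
        nan = np.full(len(samples), np.nan)
        raw = {st: nan for st in STATS}
        logged = raw
    for st in STATS:
        cols[f"{prefix}_{st}"] = raw[st]
    for st in STATS:
        cols[f"{prefix}_{st}_log2"] = logged[st]
    return pd.DataFrame(cols, index=samples)


def protein_property_features(protein: str, bundle: MultiomicsBundle) -> dict:
    """48 columns of per-protein physicochemical and annotation features."""
    row = bundle.protein_annot.loc[protein]
    length = float(row["Length"])
    if length <= 0:
        raise ValueError(f"protein {protein} has non-positive length")
    mass = float(row["Mass"])
    out: dict[str, object] = {"Length": length, "Mass": mass}
    for a in AA_ORDER:
        out[f"Aa_{a}"] = float(row[f"Aa_{a}"])
    for a in AA_ORDER:
        out[f"Aa_{a}_prop"] = float(row[f"Aa_{a}"]) / length
    out["linear_density"] = mass / length
    out["Organism"] = str(row["Organism"])
    out["Gene.encoded.by"] = str(row["Gene.encoded.by"])
    out["Version..sequence."] = str(row["Version..sequence."])
    out["Mass_log2"] = log2p(mass)
    out["linear_density_log2"] = log2p(mass / length)
    return out


def transcript_property_features(protein: str, graph: LinkageGraph,
                                 bundle: MultiomicsBundle) -> dict:
    """36 columns: six summaries of six transcript-level properties."""
    tids = graph.protein_to_transcripts.get(protein, [])
    out: dict[str, float] = {}
    if not tids:
        for prop in ("strand", "transcript_length", "percentage_gene_gc_content",
                     "cds_length", "noncds_length", "proportion_noncds_length"):
            for st in STATS:
                out[f"{prop}_{st}"] = math.nan
        return out
    annot = bundle.transcript_annot.loc[tids]
    tlen = annot["transcript_length"].to_numpy(dtype=float)
    cds = annot["cds_length"].to_numpy(dtype=float)
    if (cds > tlen).any():
        raise ValueError(f"cds_length exceeds transcript_length for {protein}")
    props = {
        "strand": np.where(annot["strand"].to_numpy() == "+", 1.0, -1.0),
        "transcript_length": tlen,
        "percentage_gene_gc_content":
            annot["percentage_gene_gc_content"].to_numpy(dtype=float),
        "cds_length": cds,
        "noncds_length": tlen - cds,
        "proportion_noncds_length": (tlen - cds) / tlen,
    }
    for prop, values in props.items():
        for st, v in zip(STATS, summarize(values).as_tuple()):
            out[f"{prop}_{st}"] = v
    return out


def stability_features(protein: str, bundle: MultiomicsBundle,
                       n_measurements: int = 9) -> dict:
    """45 columns: five summaries of each stability measurement's replicates."""
    row = bundle.protein_annot.loc[protein]
    rep_cols = [c for c in bundle.protein_annot.columns if c.startswith("stability_")]
    out: dict[str, float] = {}
    for m in range(1, n_measurements + 1):
        reps = [float(row[c]) for c in rep_cols if c.startswith(f"stability_{m}_")]
        stats = summarize(reps)
        for st in STABILITY_STATS:
            out[f"stability_{m}_{st}"] = getattr(stats, st)
    return out


# ---------------------------------------------------------------------------


def assemble(bundle: MultiomicsBundle, stringent_cutoff: float = 80.0,
             min_circ_sites: int = 7) -> DesignMatrix:
    """Build the raw design matrix: one row per (protein, sample), 196 features."""
    if bundle.protein_expr.index.has_duplicates or bundle.protein_expr.columns.has_duplicates:
        raise ValueError("duplicate (protein, sample) keys in protein_expr")
    graph = build_linkage(bundle, stringent_cutoff, min_circ_sites)
    samples = bundle.samples
    frames = []
    for protein in bundle.protein_expr.index:
        per_sample = pd.concat(
            [
                transcript_expression_features(protein, graph, bundle),
                mirna_features(protein, graph, bundle),
                circ_features(protein, graph, bundle),
            ],
            axis=1,
        )
        static = {}
        static.update(transcript_property_features(protein, graph, bundle))
        static.update(protein_property_features(protein, bundle))
        static.update(stability_features(protein, bundle))
        intensity = bundle.protein_expr.loc[protein].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            target = np.log2(intensity)
        extra = pd.DataFrame(
            {**{col: [val] * len(samples) for col, val in static.items()},
             "seq_depth": bundle.seq_depth.loc[samples].to_numpy(dtype=float),
             TARGET: target},
            index=per_sample.index)
        per_sample = pd.concat([per_sample, extra], axis=1)
        per_sample.index = pd.MultiIndex.from_arrays(
            [[protein] * len(samples), samples], names=["protein_id", "sample_id"])
        frames.append(per_sample)
    table = pd.concat(frames, axis=0)

    manifest = _default_manifest(table.columns)
    ordered = [c for c in manifest] + [TARGET]
    table = table[ordered]
    return DesignMatrix(table=table, manifest=manifest,
                        categorical=list(CATEGORICAL_COLUMNS), target=TARGET)


def _default_manifest(columns) -> dict[str, str]:
    manifest: dict[str, str] = {}
    for col in columns:
        if col == TARGET:
            continue
        if col.startswith("mrna_"):
            cat = "linear_transcript_expression"
        elif col.startswith("mirna_"):
            cat = "mirna_expression"
        elif col.startswith("mti_"):
            cat = "mti_scores"
        elif col.startswith("circ_score_"):
            cat = "circ_scores"
        elif col.startswith("circ_"):
            cat = "circ_expression"
        elif col.startswith("stability_"):
            cat = "protein_stability"
        elif col == "seq_depth":
            cat = "sequencing_depth"
        elif any(col.startswith(p) for p in (
                "strand_", "transcript_length_", "percentage_gene_gc_content_",
                "cds_length_", "noncds_length_", "proportion_noncds_length_")):
            cat = "transcript_characteristics"
        else:
            cat = "protein_characteristics"
        manifest[col] = cat
    return manifest


EXPECTED_CATEGORY_COUNTS = {
    "linear_transcript_expression": 12,
    "mirna_expression": 24,
    "transcript_characteristics": 36,
    "protein_characteristics": 48,
    "mti_scores": 12,
    "sequencing_depth": 1,
    "circ_scores": 6,
    "circ_expression": 12,
    "protein_stability": 45,
}
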