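"""Synthetic multi-omics bundles with known ground truth.

The generator emulates the data layout of a paired transcriptome/proteome
time-course experiment: a transcripts x samples TPM matrix, miRNA and
circRNA expression matrices, a protein intensity matrix with structured
missingness, and the linkage tables (protein-transcript mapping, miRNA
target interactions with confidence scores, circRNA-miRNA binding-site
counts) plus protein/transcript/GO annotation tables.

Protein abundance follows a simple generative model on the log2 scale::

    log2 I[p, s] = alpha_p
                   + beta_mrna  * log2(mean mRNA TPM of p's transcripts + 1)
                   - gamma_mirna * sum_m log2(miRNA TPM + 1)   (stringent m)
                   + Normal(0, noise_sd)

``alpha_p`` is a protein-identity intercept drawn correlated with the
protein's linear density (mass/length), so that protein-level annotation
features carry real signal.  That intercept is the mechanism behind the
gap between sample-wise and protein-wise hold-out performance: a model
evaluated on held-out *samples* can learn alpha_p from other samples of
the same protein, while a model evaluated on held-out *proteins* cannot.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "MultiomicsBundle",
    "GroundTruth",
    "generate_bundle",
    "inject_missingness",
    "simulate",
]

# Residue frequencies approximating the human proteome background.
AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_FREQ = {
    "A": 0.0702, "C": 0.0230, "D": 0.0473, "E": 0.0710, "F": 0.0365,
    "G": 0.0657, "H": 0.0263, "I": 0.0433, "K": 0.0573, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0535, "V": 0.0597, "W": 0.0122, "Y": 0.0267,
}
# Average residue masses (Da); protein mass = sum(count * mass) + water.
AA_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.0153


@dataclass
class SynthConfig:
    """Parameters of the synthetic multi-omics experiment.

    Counts and linkage densities shape the tables; the ``alpha/beta/gamma``
    block sets the generative model for protein intensity (log2 units);
    ``missing_rate`` controls abundance-dependent missingness.
    """

    n_proteins: int = 200
    n_samples: int = 20
    n_mirnas: int = 150
    n_circrnas: int = 80

    # Linkage structure (Poisson means).
    transcripts_per_protein_extra_mean: float = 0.8  # n_transcripts = 1 + Poisson
    mirna_targets_per_transcript_mean: float = 5.0
    circ_links_per_circ_mean: float = 4.0
    circ_sites_mean: float = 6.0                     # n_sites = 1 + Poisson
    mti_stringent_cutoff: float = 80.0               # score >= cutoff -> stringent

    # Log-normal expression (natural-log location/scale; within = per-sample sd).
    mrna_log_mean: float = 1.5
    mrna_log_sd: float = 1.5
    mrna_within_sd: float = 0.4
    mirna_log_mean: float = 2.5
    mirna_log_sd: float = 1.2
    mirna_within_sd: float = 0.3
    circ_log_mean: float = 0.8
    circ_log_sd: float = 1.0
    circ_within_sd: float = 0.3
    detection_floor: float = 0.25                    # draws below are reported as 0

    # Generative model for log2 protein intensity.
    alpha_sd: float = 2.0
    alpha_density_corr: float = 0.6                  # corr(alpha, linear density)
    beta_mrna: float = 0.8
    gamma_mirna: float = 0.2
    noise_sd: float = 0.5

    # Missingness.
    missing_rate: float = 0.3
    timepoint_block_missingness: bool = False
    missingness_slope: float = 1.2                   # logistic slope on z(log2 I)

    # Experiment layout and annotations.
    replicates_per_timepoint: int = 3
    n_go_terms: int = 15
    go_terms_per_protein_mean: float = 2.0
    n_stability_measurements: int = 9
    stability_replicates: int = 3

    seed: int = 7

    def validate(self) -> None:
        counts = {
            "n_proteins": self.n_proteins, "n_samples": self.n_samples,
            "n_mirnas": self.n_mirnas, "n_circrnas": self.n_circrnas,
            "replicates_per_timepoint": self.replicates_per_timepoint,
        }
        for name, value in counts.items():
            if not (isinstance(value, (int, np.integer)) and value >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        for name in ("alpha_sd", "noise_sd", "mrna_within_sd", "mirna_within_sd",
                     "circ_within_sd", "mrna_log_sd", "mirna_log_sd", "circ_log_sd"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        for name in ("beta_mrna", "gamma_mirna", "mrna_log_mean", "mirna_log_mean",
                     "circ_log_mean", "alpha_density_corr", "missingness_slope"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not (-1.0 <= self.alpha_density_corr <= 1.0):
            raise ValueError("alpha_density_corr must be in [-1, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)


@dataclass
class MultiomicsBundle:
    """One linked set of multi-omics tables for a single experiment.

    Expression tables are entities x samples; the linkage tables use long
    (edge-list) layout.  ``protein_expr`` holds label-free intensities and
    may contain NaN for unquantified cells.
    """

    transcript_expr: pd.DataFrame
    mirna_expr: pd.DataFrame
    circ_expr: pd.DataFrame
    protein_expr: pd.DataFrame
    protein_transcript_map: pd.DataFrame   # columns: protein_id, transcript_id
    mti_table: pd.DataFrame                # columns: mirna_id, transcript_id, score
    circ_site_table: pd.DataFrame          # columns: circ_id, mirna_id, n_sites
    protein_annot: pd.DataFrame            # index: protein_id
    transcript_annot: pd.DataFrame         # index: transcript_id
    go_annot: pd.DataFrame                 # columns: protein_id, go_term
    seq_depth: pd.Series                   # index: sample_id
    sample_meta: pd.DataFrame              # index: sample_id (timepoint, replicate, treatment)

    @property
    def samples(self) -> list[str]:
        return list(self.protein_expr.columns)

    def validate(self) -> None:
        cols = list(self.protein_expr.columns)
        for name in ("transcript_expr", "mirna_expr", "circ_expr"):
            other = list(getattr(self, name).columns)
            if other != cols:
                raise ValueError(f"sample columns of {name} differ from protein_expr")
        mapped = set(self.protein_transcript_map["protein_id"])
        missing = set(self.protein_expr.index) - mapped
        if missing:
            raise ValueError(f"proteins without transcript mapping: {sorted(missing)[:5]}")
        for name in ("transcript_expr", "mirna_expr", "circ_expr"):
            if (getattr(self, name).to_numpy() < 0).any():
                raise ValueError(f"negative expression in {name}")
        obs = self.protein_expr.to_numpy()
        if (obs[np.isfinite(obs)] < 0).any():
            raise ValueError("negative protein intensity")
        ta = self.transcript_annot
        if (ta["cds_length"] > ta["transcript_length"]).any():
            raise ValueError("cds_length exceeds transcript_length")
        counts = self.protein_annot[[f"Aa_{a}" for a in AA_ORDER]].sum(axis=1)
        if not np.allclose(counts, self.protein_annot["Length"]):
            raise ValueError("amino-acid counts do not sum to protein length")

    # ---- persistence (plain TSV directory + JSON) ----------------------

    _TABLES = (
        "transcript_expr", "mirna_expr", "circ_expr", "protein_expr",
        "protein_transcript_map", "mti_table", "circ_site_table",
        "protein_annot", "transcript_annot", "go_annot", "sample_meta",
    )
    _INDEXED = {
        "transcript_expr": "transcript_id", "mirna_expr": "mirna_id",
        "circ_expr": "circ_id", "protein_expr": "protein_id",
        "protein_annot": "protein_id", "transcript_annot": "transcript_id",
        "sample_meta": "sample_id",
    }

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df = getattr(self, name)
            label = self._INDEXED.get(name)
            df.to_csv(outdir / f"{name}.tsv", sep="\t",
                      index=label is not None, index_label=label)
        self.seq_depth.rename("seq_depth").to_csv(
            outdir / "seq_depth.tsv", sep="\t", index_label="sample_id")
        return outdir

    @classmethod
    def read(cls, indir: str | Path) -> "MultiomicsBundle":
        indir = Path(indir)
        kwargs = {}
        for name in cls._TABLES:
            label = cls._INDEXED.get(name)
            df = pd.read_csv(indir / f"{name}.tsv", sep="\t",
                             index_col=0 if label else None)
            if name in ("protein_transcript_map", "mti_table", "circ_site_table",
                        "go_annot"):
                df = df.reset_index(drop=True)
            kwargs[name] = df
        depth = pd.read_csv(indir / "seq_depth.tsv", sep="\t", index_col=0)["seq_depth"]
        kwargs["seq_depth"] = depth
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """The generative quantities behind a synthetic bundle."""

    alpha: pd.Series                       # per-protein intercept, log2 units
    beta_mrna: float
    gamma_mirna: float
    noise_sd: float
    true_log2_intensity: pd.DataFrame      # proteins x samples, pre-missingness
    mrna_covariate: pd.DataFrame           # log2(mean mRNA TPM + 1)
    mirna_burden: pd.DataFrame             # summed log2(miRNA TPM + 1), stringent

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        params = {
            "beta_mrna": self.beta_mrna, "gamma_mirna": self.gamma_mirna,
            "noise_sd": self.noise_sd, "alpha": self.alpha.to_dict(),
        }
        (outdir / "ground_truth.json").write_text(json.dumps(params, indent=1))
        for name in ("true_log2_intensity", "mrna_covariate", "mirna_burden"):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t",
                                       index_label="protein_id")
        return outdir

    @classmethod
    def read(cls, indir: str | Path) -> "GroundTruth":
        indir = Path(indir)
        params = json.loads((indir / "ground_truth.json").read_text())
        frames = {
            name: pd.read_csv(indir / f"{name}.tsv", sep="\t", index_col=0)
            for name in ("true_log2_intensity", "mrna_covariate", "mirna_burden")
        }
        alpha = pd.Series(params["alpha"], name="alpha")
        return cls(alpha=alpha, beta_mrna=params["beta_mrna"],
                   gamma_mirna=params["gamma_mirna"], noise_sd=params["noise_sd"],
                   **frames)


# ---------------------------------------------------------------------------


def _expression_matrix(rng, n_entities, n_samples, log_mean, log_sd, within_sd,
                       floor) -> np.ndarray:
    """Entity-level log-normal baselines plus per-sample log deviations."""
    base = rng.normal(log_mean, log_sd, size=n_entities)
    expr = np.exp(base[:, None] + rng.normal(0.0, within_sd, size=(n_entities, n_samples)))
    expr[expr < floor] = 0.0
    return expr


def _timepoints(n_samples: int, replicates: int) -> np.ndarray:
    return np.arange(n_samples) // replicates


def generate_bundle(config: SynthConfig) -> tuple[MultiomicsBundle, GroundTruth]:
    """Generate a fully observed bundle plus its ground truth.

    Deterministic: a fixed ``config.seed`` reproduces the bundle bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P, S = config.n_proteins, config.n_samples

    samples = [f"S{i + 1:02d}" for i in range(S)]
    tp_idx = _timepoints(S, config.replicates_per_timepoint)
    sample_meta = pd.DataFrame(
        {
            "timepoint": [f"T{t + 1}" for t in tp_idx],
            "replicate": [f"R{r + 1}" for r in
                          (np.arange(S) % config.replicates_per_timepoint)],
            "treatment": "UNTR",
        },
        index=pd.Index(samples, name="sample_id"),
    )

    proteins = [f"P{i + 1:04d}" for i in range(P)]
    mirnas = [f"MIR{i + 1:04d}" for i in range(config.n_mirnas)]
    circs = [f"CIRC{i + 1:04d}" for i in range(config.n_circrnas)]

    # --- protein annotation ------------------------------------------------
    lengths = np.clip(np.round(rng.lognormal(np.log(400.0), 0.5, size=P)), 50, None
                      ).astype(int)
    freqs = np.array([AA_FREQ[a] for a in AA_ORDER])
    freqs = freqs / freqs.sum()
    counts = np.vstack([rng.multinomial(n, freqs) for n in lengths])
    masses = counts @ np.array([AA_MASS[a] for a in AA_ORDER]) + WATER_MASS
    density = masses / lengths
    encoded = np.where(rng.random(P) < 0.02, "Mitochondrion", "Nucleus")
    version = rng.choice(np.arange(1, 8), size=P,
                         p=[0.35, 0.25, 0.15, 0.10, 0.07, 0.05, 0.03])
    protein_annot = pd.DataFrame(index=pd.Index(proteins, name="protein_id"))
    protein_annot["Length"] = lengths
    protein_annot["Mass"] = masses
    for j, a in enumerate(AA_ORDER):
        protein_annot[f"Aa_{a}"] = counts[:, j]
    protein_annot["Organism"] = "Human"
    protein_annot["Gene.encoded.by"] = encoded
    protein_annot["Version..sequence."] = version
    for m in range(1, config.n_stability_measurements + 1):
        for r in range(1, config.stability_replicates + 1):
            protein_annot[f"stability_{m}_rep{r}"] = rng.normal(0.0, 1.0, size=P)

    # --- transcripts and their annotation ---------------------------------
    n_tr = 1 + rng.poisson(config.transcripts_per_protein_extra_mean, size=P)
    transcript_ids, map_rows = [], []
    t = 0
    for p, k in zip(proteins, n_tr):
        for _ in range(k):
            tid = f"ENST{t + 1:08d}"
            transcript_ids.append(tid)
            map_rows.append((p, tid))
            t += 1
    protein_transcript_map = pd.DataFrame(map_rows,
                                          columns=["protein_id", "transcript_id"])
    T = len(transcript_ids)
    tlen = np.clip(np.round(rng.lognormal(np.log(2000.0), 0.6, size=T)), 200, None
                   ).astype(int)
    gc = np.clip(rng.normal(46.0, 8.0, size=T), 25.0, 75.0)
    cds = np.clip(np.round(rng.beta(5, 2, size=T) * tlen), 30, tlen).astype(int)
    transcript_annot = pd.DataFrame(
        {
            "strand": rng.choice(["+", "-"], size=T),
            "transcript_length": tlen,
            "percentage_gene_gc_content": gc,
            "cds_length": cds,
        },
        index=pd.Index(transcript_ids, name="transcript_id"),
    )

    # --- expression layers --------------------------------------------------
    transcript_expr = pd.DataFrame(
        _expression_matrix(rng, T, S, config.mrna_log_mean, config.mrna_log_sd,
                           config.mrna_within_sd, config.detection_floor),
        index=transcript_annot.index, columns=samples)
    mirna_expr = pd.DataFrame(
        _expression_matrix(rng, config.n_mirnas, S, config.mirna_log_mean,
                           config.mirna_log_sd, config.mirna_within_sd,
                           config.detection_floor),
        index=pd.Index(mirnas, name="mirna_id"), columns=samples)
    circ_expr = pd.DataFrame(
        _expression_matrix(rng, config.n_circrnas, S, config.circ_log_mean,
                           config.circ_log_sd, config.circ_within_sd,
                           config.detection_floor),
        index=pd.Index(circs, name="circ_id"), columns=samples)

    # --- linkage tables ------------------------------------------------------
    mti_rows = []
    for tid in transcript_ids:
        k = min(int(rng.poisson(config.mirna_targets_per_transcript_mean)),
                config.n_mirnas)
        if k == 0:
            continue
        targets = rng.choice(mirnas, size=k, replace=False)
        scores = rng.uniform(0.0, 100.0, size=k)
        mti_rows.extend((m, tid, s) for m, s in zip(targets, scores))
    mti_table = pd.DataFrame(mti_rows, columns=["mirna_id", "transcript_id", "score"])

    circ_rows = []
    for cid in circs:
        k = min(int(rng.poisson(config.circ_links_per_circ_mean)), config.n_mirnas)
        if k == 0:
            continue
        partners = rng.choice(mirnas, size=k, replace=False)
        sites = 1 + rng.poisson(config.circ_sites_mean, size=k)
        circ_rows.extend((cid, m, int(n)) for m, n in zip(partners, sites))
    circ_site_table = pd.DataFrame(circ_rows, columns=["circ_id", "mirna_id", "n_sites"])

    # --- GO annotation ------------------------------------------------------
    weights = 0.75 ** np.arange(config.n_go_terms)
    weights = weights / weights.sum()
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    go_rows = []
    for p in proteins:
        k = min(int(rng.poisson(config.go_terms_per_protein_mean)), config.n_go_terms)
        if k == 0:
            continue
        chosen = rng.choice(terms, size=k, replace=False, p=weights)
        go_rows.extend((p, term) for term in sorted(chosen))
    go_annot = pd.DataFrame(go_rows, columns=["protein_id", "go_term"])

    seq_depth = pd.Series(
        np.round(rng.lognormal(np.log(3.0e7), 0.2, size=S)).astype(float),
        index=pd.Index(samples, name="sample_id"), name="seq_depth")

    # --- generative model ----------------------------------------------------
    tr_of = protein_transcript_map.groupby("protein_id")["transcript_id"].agg(list)
    stringent = mti_table[mti_table["score"] >= config.mti_stringent_cutoff]
    mirnas_of_tr = stringent.groupby("transcript_id")["mirna_id"].agg(set)

    mrna_cov = np.zeros((P, S))
    burden = np.zeros((P, S))
    log2_mirna = np.log2(mirna_expr.to_numpy() + 1.0)
    mirna_pos = {m: i for i, m in enumerate(mirnas)}
    for i, p in enumerate(proteins):
        tids = tr_of[p]
        mrna_cov[i] = np.log2(transcript_expr.loc[tids].to_numpy().mean(axis=0) + 1.0)
        mset = sorted(set().union(*(mirnas_of_tr.get(t, set()) for t in tids)))
        if mset:
            burden[i] = log2_mirna[[mirna_pos[m] for m in mset]].sum(axis=0)

    z_density = np.zeros(P) if np.std(density) == 0 else (
        (density - density.mean()) / density.std())
    rho = config.alpha_density_corr
    alpha = config.alpha_sd * (rho * z_density
                               + math.sqrt(max(0.0, 1.0 - rho * rho))
                               * rng.normal(0.0, 1.0, size=P))
    true_log2 = (alpha[:, None] + config.beta_mrna * mrna_cov
                 - config.gamma_mirna * burden
                 + rng.normal(0.0, config.noise_sd, size=(P, S)))

    pidx = pd.Index(proteins, name="protein_id")
    truth = GroundTruth(
        alpha=pd.Series(alpha, index=pidx, name="alpha"),
        beta_mrna=config.beta_mrna, gamma_mirna=config.gamma_mirna,
        noise_sd=config.noise_sd,
        true_log2_intensity=pd.DataFrame(true_log2, index=pidx, columns=samples),
        mrna_covariate=pd.DataFrame(mrna_cov, index=pidx, columns=samples),
        mirna_burden=pd.DataFrame(burden, index=pidx, columns=samples),
    )
    bundle = MultiomicsBundle(
        transcript_expr=transcript_expr, mirna_expr=mirna_expr, circ_expr=circ_expr,
        protein_expr=pd.DataFrame(np.exp2(true_log2), index=pidx, columns=samples),
        protein_transcript_map=protein_transcript_map, mti_table=mti_table,
        circ_site_table=circ_site_table, protein_annot=protein_annot,
        transcript_annot=transcript_annot, go_annot=go_annot,
        seq_depth=seq_depth, sample_meta=sample_meta,
    )
    bundle.validate()
    return bundle, truth


def _calibrate_intercept(z: np.ndarray, slope: float, rate: float) -> float:
    """Intercept a such that mean(sigmoid(a - slope*z)) == rate."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(mid - slope * z)))
        if p.mean() < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def inject_missingness(bundle: MultiomicsBundle, truth: GroundTruth,
                       config: SynthConfig) -> MultiomicsBundle:
    """Mask protein intensities with abundance-dependent missingness.

    The probability of a cell being missing decreases logistically with its
    (standardized) log2 intensity, mimicking detection-limit dropout; when
    ``timepoint_block_missingness`` is set, masking decisions are made per
    (protein, timepoint) block so replicate cells go missing together.
    """
    if not (0.0 <= config.missing_rate < 1.0):
        raise ValueError(f"missing_rate must be in [0, 1), got {config.missing_rate}")
    obs = bundle.protein_expr.to_numpy()
    if np.isnan(obs).any():
        raise ValueError("protein_expr must be fully observed before masking")
    if config.missing_rate == 0.0:
        return bundle

    rng = np.random.default_rng(config.seed + 1)
    log2_i = truth.true_log2_intensity.to_numpy()
    z = (log2_i - log2_i.mean()) / log2_i.std()
    slope = config.missingness_slope

    masked = obs.copy()
    if config.timepoint_block_missingness:
        tp = _timepoints(obs.shape[1], config.replicates_per_timepoint)
        block_z = np.stack([z[:, tp == t].mean(axis=1) for t in np.unique(tp)],
                           axis=1)  # proteins x timepoints
        a = _calibrate_intercept(block_z.ravel(), slope, config.missing_rate)
        p_block = 1.0 / (1.0 + np.exp(-(a - slope * block_z)))
        block_mask = rng.random(p_block.shape) < p_block
        cell_mask = block_mask[:, tp]
    else:
        a = _calibrate_intercept(z.ravel(), slope, config.missing_rate)
        p = 1.0 / (1.0 + np.exp(-(a - slope * z)))
        cell_mask = rng.random(p.shape) < p
    masked[cell_mask] = np.nan
    protein_expr = pd.DataFrame(masked, index=bundle.protein_expr.index,
                                columns=bundle.protein_expr.columns)
    return dataclasses.replace(bundle, protein_expr=protein_expr)


def simulate(config: SynthConfig) -> tuple[MultiomicsBundle, GroundTruth]:
    """Generate a bundle and apply the configured missingness in one call."""
    bundle, truth = generate_bundle(config)
    if config.missing_rate > 0:
        bundle = inject_missingness(bundle, truth, config)
    return bundle, truth
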