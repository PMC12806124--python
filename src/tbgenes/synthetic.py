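"""Synthetic multi-tissue / tumor / single-cell / survival data generator.

The generator emulates the statistical structure the analysis pipeline
assumes, with a ground-truth ledger for recovery testing:

* **Multi-tissue bulk** - log-normal expression (log2 scale).  Each
  planted tissue-biased (TB) gene has its mean log2 expression elevated by
  ``planted_log2fc`` in its home tissue over every other tissue;
  background and stemness genes share one mean across tissues.
* **Tumor / adjacent-normal pairs** - NAT samples follow the chosen
  tissue's normal model; tumor samples are identical except the planted
  tumor-downregulated genes shift down by their planted log2 effect.  A
  per-sample latent stemness activity raises the stemness program and
  lowers the candidate genes, giving the bulk arm of the stemness screen
  something to find.
* **Single-cell trajectory** - Poisson counts with log-normal rates;
  cells carry a pseudotime in [0, 1] along which the focal tissue's TB
  program decays (with amplitude scaled by ``|stemness_coupling|``) while
  a disjoint stemness program rises.  Cluster labels partition
  pseudotime.
* **Survival** - exponential event times whose log hazard is linear in
  the negative standardized score times ``survival_coupling`` (so the
  coupling reads as log hazard ratio per score SD), with independent
  exponential censoring.

One global seed drives derived per-stage substreams, so each stage is
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tbio
from .containers import ExpressionMatrix, GeneSet, ScoreVector, TissueDesign
from .exceptions import ConfigError, DesignError, ValidationError

# fixed structural constants of the generative model (log2 units)
SC_TB_DECAY_SCALE = 2.5     # TB-program decay amplitude per unit |coupling|
SC_CANDIDATE_BOOST = 1.5    # candidates decay this much faster than other TB genes
SC_STEMNESS_RISE = 2.0      # stemness-program rise over the whole trajectory
BULK_STEMNESS_LOADING = 1.0  # loading of stemness genes on the latent activity


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort."""

    n_tissues: int = 5
    genes_tb_per_tissue: int = 40
    n_background_genes: int = 300
    n_stemness_genes: int = 50
    samples_per_tissue: int = 30
    planted_log2fc: float = 2.0
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.5
    n_tumor_pairs: int = 40
    tumor_down_log2fc: float = 1.0
    frac_tb_down: float = 0.5
    n_candidates: int = 4
    candidate_down_multiplier: float = 2.0
    n_cells: int = 2000
    n_cell_clusters: int = 5
    stemness_coupling: float = -0.8
    survival_coupling: float = 1.0
    baseline_hazard: float = 0.1
    censor_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        counts = ("n_tissues", "genes_tb_per_tissue", "n_background_genes",
                  "n_stemness_genes", "samples_per_tissue", "n_tumor_pairs",
                  "n_cells", "n_cell_clusters")
        for name in counts:
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("planted_log2fc", "tumor_down_log2fc", "baseline_log_sd",
                     "baseline_hazard", "candidate_down_multiplier"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("noise_sd", "survival_coupling", "censor_rate",
                     "n_candidates"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.frac_tb_down <= 1.0:
            raise ConfigError("frac_tb_down must lie in [0, 1]")
        if not -1.0 <= self.stemness_coupling <= 0.0:
            raise ConfigError("stemness_coupling must lie in [-1, 0]")

    def rng(self, stage: int) -> np.random.Generator:
        """Reproducible substream for one generation stage."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage,)))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SimTruth:
    """Ground-truth ledger of the planted structure.

    Invariant: candidate_genes is a subset of down_genes, which is a
    subset of the planted TB genes.
    """

    tb_gene_map: dict[str, str]            # gene -> home tissue
    down_genes: set[str]                   # planted tumor-downregulated
    candidate_genes: set[str]              # planted stemness-coupled subset
    down_log2fc: dict[str, float]          # planted downregulation magnitude
    stemness_genes: tuple[str, ...]
    background_genes: tuple[str, ...]
    baseline_log2: dict[str, float]        # gene -> baseline log2 mean
    tissues: tuple[str, ...]
    focal_tissue: str

    def __post_init__(self):
        tb = set(self.tb_gene_map)
        if not self.down_genes <= tb:
            raise ValidationError("down_genes must be planted TB genes")
        if not self.candidate_genes <= self.down_genes:
            raise ValidationError("candidate_genes must be down_genes")

    def tb_genes_for(self, tissue: str) -> list[str]:
        return sorted(g for g, t in self.tb_gene_map.items() if t == tissue)

    @property
    def all_genes(self) -> list[str]:
        return list(self.baseline_log2)

    def to_dict(self) -> dict:
        return {
            "tb_gene_map": self.tb_gene_map,
            "down_genes": sorted(self.down_genes),
            "candidate_genes": sorted(self.candidate_genes),
            "down_log2fc": self.down_log2fc,
            "stemness_genes": list(self.stemness_genes),
            "background_genes": list(self.background_genes),
            "baseline_log2": self.baseline_log2,
            "tissues": list(self.tissues),
            "focal_tissue": self.focal_tissue,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(tb_gene_map=dict(d["tb_gene_map"]),
                   down_genes=set(d["down_genes"]),
                   candidate_genes=set(d["candidate_genes"]),
                   down_log2fc={k: float(v) for k, v in d["down_log2fc"].items()},
                   stemness_genes=tuple(d["stemness_genes"]),
                   background_genes=tuple(d["background_genes"]),
                   baseline_log2={k: float(v) for k, v in d["baseline_log2"].items()},
                   tissues=tuple(d["tissues"]),
                   focal_tissue=d["focal_tissue"])


# ----------------------------------------------------------------------
def simulate_multi_tissue_bulk(config: SimConfig
                               ) -> tuple[ExpressionMatrix, TissueDesign, SimTruth]:
    """Multi-tissue normal cohort with planted tissue-biased genes.

    Returns a log2-scale genes x samples matrix, the tissue design, and
    the truth ledger (which also fixes the tumor-downregulated and
    candidate gene sets used by the later stages).
    """
    rng = config.rng(0)
    tissues = tuple(f"T{i + 1:02d}" for i in range(config.n_tissues))
    focal = tissues[0]

    tb_gene_map: dict[str, str] = {}
    for t in tissues:
        for i in range(config.genes_tb_per_tissue):
            tb_gene_map[f"TB{t}_{i:03d}"] = t
    background = tuple(f"BG_{i:04d}" for i in range(config.n_background_genes))
    stemness = tuple(f"ST_{i:03d}" for i in range(config.n_stemness_genes))
    genes = list(tb_gene_map) + list(background) + list(stemness)

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          size=len(genes))
    baseline_map = dict(zip(genes, baseline.astype(float)))

    # planted tumor-downregulated genes: a fixed fraction of each tissue's
    # TB genes; candidates are drawn from the focal tissue's down genes
    down_genes: set[str] = set()
    for t in tissues:
        tb_t = [g for g in tb_gene_map if tb_gene_map[g] == t]
        n_down = int(round(config.frac_tb_down * len(tb_t)))
        down_genes |= set(rng.choice(tb_t, size=n_down, replace=False))
    focal_down = sorted(g for g in down_genes if tb_gene_map[g] == focal)
    if config.n_candidates > len(focal_down):
        raise ConfigError(
            "n_candidates exceeds the focal tissue's downregulated TB genes; "
            "raise frac_tb_down or genes_tb_per_tissue")
    candidates = set(rng.choice(focal_down, size=config.n_candidates,
                                replace=False)) if config.n_candidates else set()
    down_log2fc = {g: config.tumor_down_log2fc *
                   (config.candidate_down_multiplier if g in candidates else 1.0)
                   for g in sorted(down_genes)}

    truth = SimTruth(tb_gene_map=tb_gene_map, down_genes=down_genes,
                     candidate_genes=candidates, down_log2fc=down_log2fc,
                     stemness_genes=stemness, background_genes=background,
                     baseline_log2=baseline_map, tissues=tissues,
                     focal_tissue=focal)

    n = config.samples_per_tissue
    sample_ids = [f"{t}_s{j + 1:02d}" for t in tissues for j in range(n)]
    design = TissueDesign(pd.Series(
        [t for t in tissues for _ in range(n)], index=sample_ids))

    mean = np.tile(baseline[:, None], (1, len(sample_ids)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g, home in tb_gene_map.items():
        cols = np.flatnonzero(np.array([t == home for t in tissues]))
        for c in cols:
            mean[gene_idx[g], c * n:(c + 1) * n] += config.planted_log2fc
    values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    matrix = ExpressionMatrix(values, genes, sample_ids, unit_scale="log2")
    return matrix, design, truth


@dataclass
class TumorNatPair:
    """Paired tumor / NAT matrices with the pairing index."""

    tumor: ExpressionMatrix
    nat: ExpressionMatrix
    pairs: pd.DataFrame  # pair_id, tumor_sample, nat_sample
    latent_stemness: np.ndarray = field(repr=False, default=None)


def simulate_tumor_nat_pairs(config: SimConfig, truth: SimTruth,
                             tissue: str) -> TumorNatPair:
    """Matched tumor / adjacent-normal pairs for one tissue.

    NAT follows the tissue's normal model; tumor is identical except that
    planted down genes of this tissue shift down by their planted log2
    effect, stemness genes load positively on a per-sample latent
    stemness activity, and candidate genes load with ``stemness_coupling``
    (negative) on the same activity.
    """
    if tissue not in truth.tissues:
        raise DesignError(f"unknown tissue {tissue!r}")
    rng = config.rng(10 + list(truth.tissues).index(tissue))
    genes = truth.all_genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    base = np.array([truth.baseline_log2[g] for g in genes])
    planted = np.zeros(len(genes))
    for g, home in truth.tb_gene_map.items():
        if home == tissue:
            planted[gene_idx[g]] = config.planted_log2fc
    n = config.n_tumor_pairs
    normal_mean = (base + planted)[:, None]

    nat_vals = normal_mean + rng.normal(0.0, config.noise_sd, (len(genes), n))
    tumor_mean = np.tile(normal_mean, (1, n))
    for g in truth.down_genes:
        if truth.tb_gene_map[g] == tissue:
            tumor_mean[gene_idx[g]] -= truth.down_log2fc[g]
    s = rng.normal(0.0, 1.0, size=n)  # latent stemness activity per tumor
    for g in truth.stemness_genes:
        tumor_mean[gene_idx[g]] += BULK_STEMNESS_LOADING * s
    for g in truth.candidate_genes:
        if truth.tb_gene_map[g] == tissue:
            tumor_mean[gene_idx[g]] += config.stemness_coupling * s
    tumor_vals = tumor_mean + rng.normal(0.0, config.noise_sd, (len(genes), n))

    pair_ids = [f"{tissue}_P{j + 1:03d}" for j in range(n)]
    nat_ids = [f"{p}_NAT" for p in pair_ids]
    tum_ids = [f"{p}_TUM" for p in pair_ids]
    pairs = pd.DataFrame({"pair_id": pair_ids, "tumor_sample": tum_ids,
                          "nat_sample": nat_ids})
    return TumorNatPair(
        tumor=ExpressionMatrix(tumor_vals, genes, tum_ids, unit_scale="log2"),
        nat=ExpressionMatrix(nat_vals, genes, nat_ids, unit_scale="log2"),
        pairs=pairs, latent_stemness=s)


def simulate_single_cell_trajectory(config: SimConfig, truth: SimTruth,
                                    pseudotime: np.ndarray | None = None
                                    ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Poisson/log-normal counts along a stemness trajectory.

    Cells carry a pseudotime in [0, 1] (uniform unless supplied).  The
    focal tissue's TB program decays linearly in pseudotime with amplitude
    ``SC_TB_DECAY_SCALE * |stemness_coupling|`` log2 units (candidates
    decay ``SC_CANDIDATE_BOOST`` times faster); the stemness program rises
    by ``SC_STEMNESS_RISE`` log2 units.  Cluster labels partition the
    pseudotime axis into equal-occupancy bins.
    """
    if config.n_cell_clusters > config.n_cells:
        raise ConfigError("n_cell_clusters must not exceed n_cells")
    rng = config.rng(2)
    n = config.n_cells
    if pseudotime is None:
        t = np.sort(rng.uniform(0.0, 1.0, size=n))
    else:
        t = np.asarray(pseudotime, dtype=float)
        if t.shape != (n,) or not np.all(np.isfinite(t)) or t.min() < 0 or t.max() > 1:
            raise ValidationError("pseudotime must be n_cells values in [0, 1]")
    genes = truth.all_genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    base = np.array([truth.baseline_log2[g] for g in genes])
    log2rate = np.tile(base[:, None], (1, n))

    amp = SC_TB_DECAY_SCALE * abs(config.stemness_coupling)
    for g in truth.tb_genes_for(truth.focal_tissue):
        a = amp * (SC_CANDIDATE_BOOST if g in truth.candidate_genes else 1.0)
        log2rate[gene_idx[g]] = base[gene_idx[g]] + config.planted_log2fc - a * t
    for g in truth.stemness_genes:
        log2rate[gene_idx[g]] = base[gene_idx[g]] + SC_STEMNESS_RISE * t

    log2rate += rng.normal(0.0, config.noise_sd, size=log2rate.shape)
    counts = rng.poisson(np.exp2(log2rate)).astype(float)
    cell_ids = [f"cell_{i + 1:05d}" for i in range(n)]

    if np.ptp(t) == 0:
        cluster_idx = np.zeros(n, dtype=int)
    else:
        order_rank = pd.Series(t).rank(method="first")
        cluster_idx = pd.qcut(order_rank, config.n_cell_clusters,
                              labels=False).to_numpy()
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "cluster": [f"C{i + 1}" for i in cluster_idx],
        "pseudotime": t,
    })
    matrix = ExpressionMatrix(counts, genes, cell_ids, unit_scale="linear")
    return matrix, cells


def simulate_survival(scores: ScoreVector | pd.Series,
                      config: SimConfig) -> pd.DataFrame:
    """Exponential survival times coupled to a per-subject score.

    The hazard is ``baseline_hazard * exp(-survival_coupling * z)`` where
    z is the standardized score, so ``survival_coupling`` is the log
    hazard ratio per score SD and higher scores mean longer survival.
    Censoring times are independent exponentials at ``censor_rate``.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else pd.Series(scores)
    x = s.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("scores must be finite")
    rng = config.rng(3)
    sd = x.std(ddof=0)
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    hazard = config.baseline_hazard * np.exp(-config.survival_coupling * z)
    times = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, size=len(x))
    else:
        censor = np.full(len(x), np.inf)
    observed = np.minimum(times, censor)
    event = (times <= censor).astype(int)
    return pd.DataFrame({"subject_id": s.index.astype(str),
                         "time": np.maximum(observed, 1e-12),
                         "event": event})


# ----------------------------------------------------------------------
@dataclass
class SimStudy:
    """Everything one synthetic study produces, ready for the pipeline."""

    config: SimConfig
    truth: SimTruth
    bulk: ExpressionMatrix
    design: TissueDesign
    tumor_nat: TumorNatPair
    sc_counts: ExpressionMatrix
    sc_cells: pd.DataFrame
    gene_sets: dict[str, GeneSet]
    tb_scores: ScoreVector
    survival: pd.DataFrame


def simulate_study(config: SimConfig) -> SimStudy:
    """Run every generation stage for the focal tissue."""
    from .scoring import score_signature

    bulk, design, truth = simulate_multi_tissue_bulk(config)
    pair = simulate_tumor_nat_pairs(config, truth, truth.focal_tissue)
    sc_counts, sc_cells = simulate_single_cell_trajectory(config, truth)
    gene_sets = {f"TB_{t}": GeneSet(f"TB_{t}", tuple(truth.tb_genes_for(t)),
                                    description=f"planted TB genes of {t}")
                 for t in truth.tissues}
    gene_sets["STEMNESS"] = GeneSet("STEMNESS", truth.stemness_genes,
                                    description="planted stemness program")
    tb_scores = score_signature(pair.tumor,
                                gene_sets[f"TB_{truth.focal_tissue}"],
                                method="zmean")
    surv = simulate_survival(tb_scores, config)
    return SimStudy(config=config, truth=truth, bulk=bulk, design=design,
                    tumor_nat=pair, sc_counts=sc_counts, sc_cells=sc_cells,
                    gene_sets=gene_sets, tb_scores=tb_scores, survival=surv)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(study: SimStudy, directory) -> dict:
    """Write every study input as plain text and return a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tbio.write_expression_tsv(study.bulk, directory / "bulk_expression.tsv")
    tbio.write_design_tsv(study.design, directory / "tissue_design.tsv")
    tbio.write_expression_tsv(study.tumor_nat.tumor, directory / "tumor.tsv")
    tbio.write_expression_tsv(study.tumor_nat.nat, directory / "nat.tsv")
    study.tumor_nat.pairs.to_csv(directory / "pairs.tsv", sep="\t", index=False)
    mtx_files = tbio.write_mtx_bundle(study.sc_counts, directory)
    study.sc_cells.to_csv(directory / "sc_cells.tsv", sep="\t", index=False)
    tbio.write_gmt(study.gene_sets, directory / "gene_sets.gmt")
    study.tb_scores.to_frame().to_csv(directory / "tb_scores.tsv", sep="\t",
                                      index=False)
    tbio.write_survival_tsv(study.survival, directory / "survival.tsv")
    tbio.write_json(study.truth.to_dict(), directory / "truth.json")

    files = ["bulk_expression.tsv", "tissue_design.tsv", "tumor.tsv", "nat.tsv",
             "pairs.tsv", "sc_cells.tsv", "gene_sets.gmt", "tb_scores.tsv",
             "survival.tsv", "truth.json"] + [f.name for f in mtx_files]
    manifest = {
        "unit_scales": {"bulk_expression.tsv": "log2", "tumor.tsv": "log2",
                        "nat.tsv": "log2", "sc_matrix.mtx": "linear"},
        "files": {name: _sha256(directory / name) for name in sorted(files)},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def config_with(config: SimConfig, **overrides) -> SimConfig:
    """Return a copy of ``config`` with fields replaced (validated)."""
    return replace(config, **overrides)
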