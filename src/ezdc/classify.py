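"""Maternal / zygotic / maternal+zygotic gene classification.

Genes with enough allele-informative reads are clustered (k-medians,
city-block distance, coordinate-wise median centroids) on their
allele-resolved female time profiles: the 16-vector of maternal-allele
and paternal-allele component RPKM over the 8 stages, log2(x+1)
transformed.  Each cluster is labeled by simple kinetic rules applied to
its back-transformed centroid:

* maternal — no paternal signal and the maternal level declines from
  cycle 10 to the end of cycle 14;
* zygotic — no mRNA at cycle 10 and paternal signal appears;
* maternal+zygotic — maternal mRNA present at cycle 10 and paternal
  signal appears over time.

Genes lacking strain-distinguishing SNPs inherit the label of the
cluster whose mean total-expression profile best correlates with their
own (Pearson, strictly > 0.8 by default).  All assignment uses female
samples only: the male X has no paternal allele to observe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import AllelicCounts, ExpressionData, PartitionedExpression
from .stages import STAGES

__all__ = [
    "ClassifyConfig",
    "GeneProfiles",
    "KMediansResult",
    "ClusterModel",
    "build_profiles",
    "select_informative",
    "kmedians",
    "label_cluster",
    "propagate",
    "classify_all",
]

CLASSES = ("maternal", "zygotic", "maternal_zygotic", "unclassified")


@dataclass(frozen=True)
class ClassifyConfig:
    k: int = 20
    seed: int = 17
    n_restarts: int = 20
    #: minimum allele-informative reads (summed over the 12 female
    #: samples) for a gene to enter clustering directly.
    min_reads: int = 10
    #: propagation requires correlation strictly greater than this.
    r_threshold: float = 0.8
    #: detection floor (RPKM) for the cluster labeling rules.
    epsilon: float = 0.5
    correlation: str = "pearson"  # or "spearman"
    #: correlate log2(x+1) profiles during propagation (linear if False).
    profile_log: bool = True


@dataclass
class GeneProfiles:
    """Replicate-averaged female stage profiles per gene (length-8 each)."""

    maternal: pd.DataFrame
    paternal: pd.DataFrame
    total: pd.DataFrame
    informative_reads: pd.Series


@dataclass
class KMediansResult:
    labels: np.ndarray
    centers: np.ndarray
    cost: float
    n_iter: int


@dataclass
class ClusterModel:
    """Fitted, labeled clustering used for direct and propagated assignment."""

    centers_log: np.ndarray  # k x 16, log2(RPKM+1)
    labels: list[str]
    mean_total: np.ndarray  # k x 8, linear RPKM
    sizes: np.ndarray
    cost: float
    config: ClassifyConfig = field(default_factory=ClassifyConfig)

    @property
    def centers_linear(self) -> np.ndarray:
        return np.maximum(np.exp2(self.centers_log) - 1.0, 0.0)

    @property
    def centroid_total(self) -> np.ndarray:
        """k x 8 total-expression profile of each centroid (linear RPKM).

        The robust analogue of the member-mean total profile
        (``mean_total``): the sum of the maternal and paternal halves of
        the back-transformed median centroid.  Used as the propagation
        reference — the arithmetic member mean is dominated by the
        largest-amplitude genes in a cluster and blurs profile shape.
        """
        lin = self.centers_linear
        return lin[:, :8] + lin[:, 8:]


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def build_profiles(
    part: PartitionedExpression,
    expr: ExpressionData,
    counts: AllelicCounts,
) -> GeneProfiles:
    """Female-only stage profiles with read-weighted allele pooling.

    For each stage, replicate RPKM is averaged and the allele split is
    taken from reads pooled across that stage's female replicates; a
    stage with no informative reads falls back to the gene's overall
    female allele share (its component values there are negligible by
    construction whenever this matters).
    """
    meta = expr.samples
    fem = meta.index[meta["sex"] == "F"]
    missing = set(STAGES) - set(meta.loc[fem, "stage"])
    if missing:
        raise ValueError(f"missing female samples for stage(s) {sorted(missing)}")
    m_reads = counts.maternal[fem]
    p_reads = counts.paternal[fem]
    rpkm = expr.rpkm[fem]
    gene_m = m_reads.sum(axis=1).to_numpy(dtype=float)
    gene_p = p_reads.sum(axis=1).to_numpy(dtype=float)
    gene_tot = gene_m + gene_p
    with np.errstate(invalid="ignore", divide="ignore"):
        gene_share = np.where(gene_tot > 0, gene_m / np.maximum(gene_tot, 1), np.nan)

    mat, pat, tot = {}, {}, {}
    stages_of = meta.loc[fem, "stage"]
    for stage in STAGES:
        cols = fem[stages_of == stage]
        mean_rpkm = rpkm[cols].mean(axis=1).to_numpy()
        ms = m_reads[cols].sum(axis=1).to_numpy(dtype=float)
        ps = p_reads[cols].sum(axis=1).to_numpy(dtype=float)
        st_tot = ms + ps
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(st_tot > 0, ms / np.maximum(st_tot, 1), gene_share)
        mat[stage] = mean_rpkm * share
        pat[stage] = mean_rpkm * (1.0 - share)
        tot[stage] = mean_rpkm
    idx = expr.rpkm.index
    return GeneProfiles(
        maternal=pd.DataFrame(mat, index=idx)[list(STAGES)],
        paternal=pd.DataFrame(pat, index=idx)[list(STAGES)],
        total=pd.DataFrame(tot, index=idx)[list(STAGES)],
        informative_reads=pd.Series(gene_tot.astype(int), index=idx, name="informative_reads"),
    )


def select_informative(profiles: GeneProfiles, min_reads: int = 10) -> pd.Index:
    """Genes with at least ``min_reads`` informative reads (females, summed)."""
    keep = profiles.informative_reads >= min_reads
    return profiles.informative_reads.index[keep]


# ---------------------------------------------------------------------------
# k-medians
# ---------------------------------------------------------------------------

def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.abs(X[:, None, :] - centers[None, :, :]).sum(axis=2)
    lab = d.argmin(axis=1)
    return lab, d[np.arange(len(X)), lab]


def kmedians(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 200,
) -> KMediansResult:
    """k-medians clustering: city-block distance, coordinate-wise medians.

    Lloyd-style alternation from random point initializations, keeping
    the best of ``n_restarts`` runs; the objective (total L1 distance of
    points to their cluster median) never increases within a run.  An
    emptied cluster is reseeded with the point farthest from its current
    centroid.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= n points, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    best: KMediansResult | None = None
    for _ in range(n_restarts):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        lab, dist = _assign(X, centers)
        for it in range(max_iter):
            for j in range(k):
                members = X[lab == j]
                if len(members):
                    centers[j] = np.median(members, axis=0)
                else:
                    centers[j] = X[int(np.argmax(dist))]
            new_lab, dist = _assign(X, centers)
            if np.array_equal(new_lab, lab):
                break
            lab = new_lab
        cost = float(dist.sum())
        if best is None or cost < best.cost:
            best = KMediansResult(lab.copy(), centers.copy(), cost, it + 1)
    return best


# ---------------------------------------------------------------------------
# labeling and propagation
# ---------------------------------------------------------------------------

def label_cluster(centroid_linear: np.ndarray, epsilon: float = 0.5) -> str:
    """Kinetic label for one back-transformed (linear RPKM) centroid.

    ``centroid_linear`` concatenates the maternal 8-vector and the
    paternal 8-vector in stage order.  ``epsilon`` is the detection
    floor: signal below it counts as absent.
    """
    c = np.asarray(centroid_linear, dtype=float)
    if c.shape != (16,):
        raise ValueError("centroid must have 16 coordinates (maternal 8 + paternal 8)")
    mat, pat = c[:8], c[8:]
    paternal_seen = pat.max() >= epsilon
    if not paternal_seen and mat[-1] < mat[0]:
        return "maternal"
    if mat[0] + pat[0] < epsilon and paternal_seen:
        return "zygotic"
    if mat[0] >= epsilon and paternal_seen:
        return "maternal_zygotic"
    return "unclassified"


def _corr(x: np.ndarray, Y: np.ndarray, kind: str) -> np.ndarray:
    """Correlation of one profile against each row of Y; NaN where undefined."""
    if kind == "spearman":
        x = rankdata(x)
        Y = np.apply_along_axis(rankdata, 1, Y)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / (sx * sy)
    return r


def propagate(
    total_profile: np.ndarray,
    model: ClusterModel,
    r_threshold: float | None = None,
) -> tuple[str, int, float]:
    """Assign a SNP-free gene by correlation with cluster reference profiles.

    The reference is each cluster's centroid total-expression profile
    (see :attr:`ClusterModel.centroid_total`), compared on the log2(x+1)
    scale by default.

    Returns (label, cluster_id, r).  The gene takes the label of its
    best-correlated cluster when r exceeds the threshold strictly;
    otherwise ('unclassified', -1, r).  A constant (zero-variance)
    profile has undefined correlation and stays unclassified.  Ties in
    the best correlation resolve to the lower cluster index.
    """
    cfg = model.config
    thr = cfg.r_threshold if r_threshold is None else r_threshold
    x = np.asarray(total_profile, dtype=float)
    ref = model.centroid_total
    if cfg.profile_log:
        x = np.log2(x + 1.0)
        ref = np.log2(ref + 1.0)
    if np.ptp(x) == 0 or not np.isfinite(x).all():
        return "unclassified", -1, float("nan")
    r = _corr(x, ref, cfg.correlation)
    r = np.where(np.isfinite(r), r, -np.inf)
    best = int(np.argmax(r))
    if r[best] > thr:
        return model.labels[best], best, float(r[best])
    return "unclassified", -1, float(r[best])


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def fit_cluster_model(
    profiles: GeneProfiles,
    informative: pd.Index,
    cfg: ClassifyConfig,
) -> tuple[ClusterModel, pd.Series]:
    """Cluster the informative genes and label every cluster."""
    M = profiles.maternal.loc[informative].to_numpy()
    P = profiles.paternal.loc[informative].to_numpy()
    X = np.log2(np.concatenate([M, P], axis=1) + 1.0)
    fit = kmedians(X, cfg.k, seed=cfg.seed, n_restarts=cfg.n_restarts)
    T = profiles.total.loc[informative].to_numpy()
    labels, mean_total, sizes = [], [], []
    for j in range(cfg.k):
        members = fit.labels == j
        centroid_lin = np.maximum(np.exp2(fit.centers[j]) - 1.0, 0.0)
        labels.append(label_cluster(centroid_lin, cfg.epsilon))
        mean_total.append(T[members].mean(axis=0) if members.any() else np.zeros(8))
        sizes.append(int(members.sum()))
    model = ClusterModel(
        centers_log=fit.centers,
        labels=labels,
        mean_total=np.asarray(mean_total),
        sizes=np.asarray(sizes),
        cost=fit.cost,
        config=cfg,
    )
    assignment = pd.Series(fit.labels, index=informative, name="cluster_id")
    return model, assignment


def classify_all(
    part: PartitionedExpression,
    expr: ExpressionData,
    counts: AllelicCounts,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> tuple[pd.DataFrame, ClusterModel]:
    """Classify every gene; returns (gene class table, fitted model).

    Table columns: ``class`` in {maternal, zygotic, maternal_zygotic,
    unclassified}; ``route`` in {direct, propagated, none};
    ``cluster_id`` (-1 off-model); ``correlation`` (propagation r, NaN
    for direct).  Direct route: genes with >= min_reads informative
    reads, assigned through clustering.  Propagated route: remaining
    genes with a cluster correlation strictly above the threshold.
    """
    meta = expr.samples
    missing = [
        (sex, st)
        for sex in ("F",)
        for st in STAGES
        if not ((meta["sex"] == sex) & (meta["stage"] == st)).any()
    ]
    if missing:
        raise ValueError(f"missing samples for {missing}")
    profiles = build_profiles(part, expr, counts)
    informative = select_informative(profiles, cfg.min_reads)
    if len(informative) < cfg.k:
        raise ValueError(
            f"only {len(informative)} informative genes for k={cfg.k} clusters"
        )
    model, assignment = fit_cluster_model(profiles, informative, cfg)

    table = pd.DataFrame(
        {
            "class": "unclassified",
            "route": "none",
            "cluster_id": -1,
            "correlation": np.nan,
        },
        index=expr.rpkm.index,
    )
    table.loc[informative, "class"] = [model.labels[c] for c in assignment]
    table.loc[informative, "route"] = "direct"
    table.loc[informative, "cluster_id"] = assignment

    rest = table.index.difference(informative, sort=False)
    T = profiles.total.loc[rest].to_numpy()
    for gid, prof in zip(rest, T):
        label, cid, r = propagate(prof, model)
        if label != "unclassified":
            table.loc[gid, ["class", "route", "cluster_id"]] = [label, "propagated", cid]
        table.loc[gid, "correlation"] = r
    table["cluster_id"] = table["cluster_id"].astype(int)
    table.index.name = "gene_id"
    return table, model
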