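"""Tissue/stage specificity of isoform expression.

The specificity score of an isoform follows the Jensen-Shannon construction
used for transcript tissue specificity in the Cufflinks literature: with the
isoform's expression pattern normalized to a distribution p over tissues and
e_t the ideal single-tissue pattern (all mass on tissue t),

    score_t = 1 - sqrt(JSD(p, e_t)),

where JSD is the Jensen-Shannon divergence with base-2 entropy (so scores
lie in [0, 1]; 1 means perfectly tissue-exclusive). Exclusive isoforms are
those detected (>= presence threshold) in exactly one tissue or stage; trend
clustering partitions differentially expressed isoforms into up/down groups
across ordered developmental stages.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


class ExpressionMatrix:
    """Isoform x sample abundances plus sample -> tissue/stage mappings.

    Values are non-negative FPKM-like abundances; isoform ids are unique.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_tissue: Mapping[str, str] | None = None,
        sample_stage: Mapping[str, str] | None = None,
        gene_map: Mapping[str, str] | None = None,
    ) -> None:
        if values.index.duplicated().any():
            raise ValueError("duplicate isoform ids in expression matrix")
        if (values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        self.values = values.astype(float)
        self.sample_tissue = dict(sample_tissue or {})
        self.sample_stage = dict(sample_stage or {})
        self.gene_map = dict(gene_map or {})

    @property
    def isoforms(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, mapping: Mapping[str, str]) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = defaultdict(list)
        for sample in self.samples:
            if sample in mapping:
                groups[mapping[sample]].append(sample)
        return dict(groups)

    def group_means(self, mapping: Mapping[str, str]) -> pd.DataFrame:
        """Mean abundance per group (tissue or stage), isoforms x groups."""
        groups = self.group_samples(mapping)
        return pd.DataFrame(
            {g: self.values[samples].mean(axis=1) for g, samples in groups.items()}
        )

    def tissue_means(self) -> pd.DataFrame:
        return self.group_means(self.sample_tissue)

    def stage_means(self) -> pd.DataFrame:
        return self.group_means(self.sample_stage)

    # -- I/O: matrix TSV plus a sidecar mapping samples to tissue/stage ----

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="isoform_id")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                fh.write("sample\ttissue\tstage\n")
                for sample in self.samples:
                    fh.write(
                        f"{sample}\t{self.sample_tissue.get(sample, '')}\t"
                        f"{self.sample_stage.get(sample, '')}\n"
                    )

    @classmethod
    def from_tsv(
        cls, path: str | Path, sidecar: str | Path | None = None
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col="isoform_id")
        tissue: dict[str, str] = {}
        stage: dict[str, str] = {}
        if sidecar is not None:
            side = pd.read_csv(sidecar, sep="\t", dtype=str).fillna("")
            for _, row in side.iterrows():
                if row["tissue"]:
                    tissue[row["sample"]] = row["tissue"]
                if row["stage"]:
                    stage[row["sample"]] = row["stage"]
        return cls(values, tissue, stage)


# ---------------------------------------------------------------------------
# Jensen-Shannon specificity
# ---------------------------------------------------------------------------


def _entropy2(p: np.ndarray) -> float:
    """Base-2 Shannon entropy with the 0*log0 := 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD(p, q) = H((p+q)/2) - (H(p) + H(q))/2 with base-2 entropy."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2.0
    return max(0.0, _entropy2(m) - (_entropy2(p) + _entropy2(q)) / 2.0)


@dataclass
class TissueSpecificityResult:
    isoform_id: str | None
    pattern: pd.Series | None  # normalized expression pattern (sums to 1)
    scores: pd.Series | None  # per-tissue JS scores
    max_score: float | None
    argmax_tissue: str | None
    undefined: bool = False


def js_specificity(
    expression: Mapping[str, float] | pd.Series,
    isoform_id: str | None = None,
) -> TissueSpecificityResult:
    """JS specificity scores of one isoform's expression across tissues.

    All-zero vectors are flagged undefined (and should be excluded from
    score distributions). The score is scale-invariant and equals 1 exactly
    when expression is confined to a single tissue; argmax ties break
    lexicographically by tissue label.
    """
    vec = pd.Series(expression, dtype=float)
    if (vec < 0).any():
        raise ValueError("expression vector must be non-negative")
    total = vec.sum()
    if total == 0:
        return TissueSpecificityResult(
            isoform_id, None, None, None, None, undefined=True
        )
    p = vec / total
    scores = {}
    for tissue in vec.index:
        e_t = np.zeros(len(vec))
        e_t[list(vec.index).index(tissue)] = 1.0
        scores[tissue] = 1.0 - float(np.sqrt(js_divergence(p.values, e_t)))
    score_series = pd.Series(scores)
    best = min(
        score_series.index, key=lambda t: (-score_series[t], str(t))
    )
    return TissueSpecificityResult(
        isoform_id=isoform_id,
        pattern=p,
        scores=score_series,
        max_score=float(score_series[best]),
        argmax_tissue=best,
    )


def tissue_specificity_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Max JS score and argmax tissue per isoform (tissue-mean patterns).

    Isoforms with all-zero expression are flagged undefined in the table.
    """
    means = matrix.tissue_means()
    rows = []
    for isoform in means.index:
        res = js_specificity(means.loc[isoform], isoform)
        rows.append(
            {
                "isoform_id": isoform,
                "max_score": np.nan if res.undefined else res.max_score,
                "argmax_tissue": "" if res.undefined else res.argmax_tissue,
                "undefined": res.undefined,
            }
        )
    return pd.DataFrame(rows).set_index("isoform_id")


def compare_score_distributions(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of score distributions.

    Returns (D, p) with D = sup |ECDF_a - ECDF_b| and the asymptotic
    p-value.
    """
    if len(scores_a) == 0 or len(scores_b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(scores_a, scores_b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Exclusive isoforms
# ---------------------------------------------------------------------------


@dataclass
class ExclusiveSet:
    """Per-group exclusive isoforms plus all combination counts for Venns."""

    exclusive: dict[str, set[str]]
    combination_counts: dict[frozenset, int]
    presence: pd.DataFrame  # isoforms x groups, boolean

    def counts(self) -> dict[str, int]:
        return {g: len(ids) for g, ids in self.exclusive.items()}

    def combination_counts_json(self) -> dict[str, int]:
        return {
            "&".join(sorted(k)): v
            for k, v in sorted(
                self.combination_counts.items(), key=lambda kv: sorted(kv[0])
            )
        }


def exclusive_isoforms(
    matrix: ExpressionMatrix,
    groups: Mapping[str, str] | None = None,
    presence_threshold: float = 0.1,
) -> ExclusiveSet:
    """Isoforms detected in exactly one group (tissue by default).

    An isoform is present in a group iff any sample of that group reaches
    ``presence_threshold``. Exclusive sets are pairwise disjoint by
    construction; the full combination counts support Venn rendering.
    """
    mapping = groups if groups is not None else matrix.sample_tissue
    group_samples = matrix.group_samples(mapping)
    empty = sorted(set(mapping.values()) - set(group_samples))
    if empty:
        raise ValueError(f"groups with no samples in the matrix: {', '.join(empty)}")
    if len(group_samples) < 2:
        raise ValueError("need at least two groups")
    presence = pd.DataFrame(
        {
            g: (matrix.values[samples] >= presence_threshold).any(axis=1)
            for g, samples in group_samples.items()
        }
    )
    exclusive = {
        g: set(presence.index[presence[g] & (presence.sum(axis=1) == 1)])
        for g in presence.columns
    }
    combo_counts: dict[frozenset, int] = {}
    group_names = list(presence.columns)
    membership = presence.apply(
        lambda row: frozenset(g for g in group_names if row[g]), axis=1
    )
    for r in range(1, len(group_names) + 1):
        for combo in combinations(group_names, r):
            key = frozenset(combo)
            combo_counts[key] = int((membership == key).sum())
    return ExclusiveSet(exclusive, combo_counts, presence)


def stage_specific(
    matrix: ExpressionMatrix,
    stages: Sequence[str],
    presence_threshold: float = 0.1,
    gene_map: Mapping[str, str] | None = None,
) -> tuple[ExclusiveSet, dict[str, int]]:
    """Stage-exclusive isoforms plus the count of their parent genes."""
    stage_mapping = {
        s: st for s, st in matrix.sample_stage.items() if st in set(stages)
    }
    excl = exclusive_isoforms(matrix, stage_mapping, presence_threshold)
    genes = gene_map if gene_map is not None else matrix.gene_map
    gene_counts = {}
    for stage in stages:
        ids = excl.exclusive.get(stage, set())
        gene_counts[stage] = len({genes.get(i, i) for i in ids})
    return excl, gene_counts


# ---------------------------------------------------------------------------
# Time-course trend clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendCluster:
    isoform_id: str
    label: str  # 'up' | 'down'
    z_profile: tuple[float, ...]


def select_differential(
    matrix: ExpressionMatrix,
    stages: Sequence[str],
    min_fold: float = 2.0,
    min_max_mean: float = 1.0,
) -> list[str]:
    """Stand-in differential rule: max/min stage-mean fold change >= min_fold
    and max stage mean >= min_max_mean (a zero minimum always passes the
    fold-change test)."""
    means = matrix.stage_means()[list(stages)]
    eps = 1e-12
    fold = means.max(axis=1) / means.min(axis=1).clip(lower=eps)
    keep = (fold >= min_fold) & (means.max(axis=1) >= min_max_mean)
    return list(means.index[keep])


def timecourse_clusters(
    profiles: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
) -> list[TrendCluster]:
    """Cluster per-isoform stage profiles into up/down trend groups.

    ``profiles`` is isoforms x ordered stages (mean abundance per stage).
    Profiles are z-scored per isoform, clustered with seeded k-means
    (k-means++ init, 10 restarts), and clusters are relabeled 'up'/'down'
    by the sign of the mean first-to-last z difference. Constant (zero
    variance) profiles are excluded and logged.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least two ordered stages")
    std = profiles.std(axis=1, ddof=0)
    constant = list(profiles.index[std == 0])
    if constant:
        logger.info("excluding %d constant profiles from clustering", len(constant))
    usable = profiles.loc[std > 0]
    if usable.empty:
        return []
    z = usable.sub(usable.mean(axis=1), axis=0).div(std[std > 0], axis=0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignments = km.fit_predict(z.values)
    labels = {}
    for cluster in range(k):
        member_z = z.values[assignments == cluster]
        mean_delta = float(np.mean(member_z[:, -1] - member_z[:, 0]))
        labels[cluster] = "up" if mean_delta > 0 else "down"
    return [
        TrendCluster(isoform, labels[c], tuple(z.loc[isoform]))
        for isoform, c in zip(usable.index, assignments)
    ]
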