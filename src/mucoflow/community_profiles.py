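"""Post-ASV-table compositional processing.

Starts from an integer feature table (samples x taxa, as produced by any
amplicon denoiser) and provides the downstream steps of a 16S analysis:
low-abundance filtering, relative abundance, centered log-ratio (CLR)
transform, alpha diversity, rarefaction, core-genus detection and
group-maximum normalization of genus abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "CompositionTable",
    "FilterReport",
    "filter_low_abundance",
    "relative_abundance",
    "clr_transform",
    "alpha_diversity",
    "rarefy",
    "core_genera",
    "group_max_normalize",
    "read_feature_table",
    "read_taxonomy",
    "read_groups",
]


@dataclass
class AbundanceTable:
    """Integer count table, samples on rows and taxa on columns.

    taxonomy maps taxon id -> semicolon-delimited lineage (or plain genus
    label); sample_meta maps sample id -> group label.
    """

    counts: pd.DataFrame
    taxonomy: dict | None = None
    sample_meta: dict | None = None

    def __post_init__(self):
        self.counts = pd.DataFrame(self.counts)
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate taxon ids")
        vals = self.counts.to_numpy()
        if vals.size and ((vals < 0).any() or not np.all(np.isfinite(vals))):
            raise ValueError("counts must be finite and nonnegative")

    @property
    def sample_ids(self):
        return list(self.counts.index)

    @property
    def taxon_ids(self):
        return list(self.counts.columns)

    def genus_of(self, taxon: str) -> str:
        if self.taxonomy is None:
            raise ValueError("taxonomy not available")
        lineage = self.taxonomy[taxon]
        return lineage.split(";")[-1].strip()


@dataclass
class CompositionTable:
    """Real-valued table on the same axes: relative abundances or CLR."""

    values_frame: pd.DataFrame
    kind: str  # "relative" or "clr"
    taxonomy: dict | None = None
    sample_meta: dict | None = None

    @property
    def sample_ids(self):
        return list(self.values_frame.index)

    @property
    def taxon_ids(self):
        return list(self.values_frame.columns)


@dataclass(frozen=True)
class FilterReport:
    removed: list
    n_before: int
    n_after: int


def filter_low_abundance(
    table: AbundanceTable, min_samples: int = 2, min_total: int = 10
) -> tuple[AbundanceTable, FilterReport]:
    """Drop rare taxa: keep a taxon iff it is present (count > 0) in at
    least ``min_samples`` samples AND its total count is >= ``min_total``.

    The sample axis is unchanged; the removed taxa are reported.
    """
    if min_samples < 0 or min_total < 0:
        raise ValueError("thresholds must be >= 0")
    if table.counts.empty:
        raise ValueError("empty table")
    counts = table.counts
    prevalence = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    keep = (prevalence >= min_samples) & (totals >= min_total)
    removed = [t for t, k in keep.items() if not k]
    filtered = AbundanceTable(
        counts.loc[:, keep], taxonomy=table.taxonomy, sample_meta=table.sample_meta
    )
    return filtered, FilterReport(removed, counts.shape[1], int(keep.sum()))


def relative_abundance(table: AbundanceTable) -> CompositionTable:
    """Divide each sample's counts by its total; rows sum to 1."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    rel = table.counts.div(totals, axis=0)
    return CompositionTable(rel, "relative", table.taxonomy, table.sample_meta)


def clr_transform(table: AbundanceTable, pseudocount: float = 1.0) -> CompositionTable:
    """Centered log-ratio transform with an additive pseudocount.

    clr_i = log(x_i + c) - mean_j log(x_j + c), per sample; rows sum to 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    frame = pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)
    return CompositionTable(frame, "clr", table.taxonomy, table.sample_meta)


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Observed taxa and Shannon index (natural log) per sample."""
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total samples: {bad}")
    observed = (counts > 0).sum(axis=1)
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"observed_taxa": observed.astype(int), "shannon": shannon},
        index=table.counts.index,
    )


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample without replacement to exactly ``depth`` reads."""
    totals = table.counts.sum(axis=1)
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"depth {depth} exceeds totals of samples: {list(short.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy(dtype=np.int64))
    for i, (_, row) in enumerate(table.counts.iterrows()):
        out[i] = rng.multivariate_hypergeometric(
            row.to_numpy(dtype=np.int64), depth
        )
    frame = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return AbundanceTable(frame, taxonomy=table.taxonomy, sample_meta=table.sample_meta)


def _genus_frame(table: CompositionTable) -> pd.DataFrame:
    if table.taxonomy is None:
        raise ValueError("genus-level taxonomy required")
    genus = {t: table.taxonomy[t].split(";")[-1].strip() for t in table.taxon_ids}
    return table.values_frame.T.groupby(
        [genus[t] for t in table.taxon_ids]
    ).sum().T


def core_genera(table: CompositionTable, prevalence: float) -> dict[str, set]:
    """Per-group core genera: detected (> 0) in >= ``prevalence`` fraction
    of the group's samples."""
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must lie in (0, 1]")
    if table.sample_meta is None:
        raise ValueError("sample group labels required")
    gframe = _genus_frame(table)
    groups: dict[str, set] = {}
    labels = pd.Series({s: table.sample_meta[s] for s in gframe.index})
    for group, members in labels.groupby(labels):
        sub = gframe.loc[members.index]
        frac = (sub > 0).mean(axis=0)
        groups[group] = set(frac[frac >= prevalence].index)
    return groups


def group_max_normalize(table: CompositionTable, groups: dict | None = None) -> pd.DataFrame:
    """Per-genus group means scaled so the highest group is 100 %.

    Returns genera x groups percentages; a genus absent everywhere is
    reported as NaN (undefined), not zero.
    """
    meta = groups if groups is not None else table.sample_meta
    if meta is None:
        raise ValueError("group labels required")
    gframe = _genus_frame(table)
    labels = pd.Series({s: meta[s] for s in gframe.index})
    means = gframe.groupby(labels).mean().T  # genera x groups
    maxima = means.max(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pct = means.div(maxima, axis=0) * 100.0
    pct[maxima == 0] = np.nan
    return pct


def read_feature_table(path, taxonomy_path=None, groups_path=None) -> AbundanceTable:
    """Read a TSV feature table (first column sample id, taxon ids as header)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    meta = read_groups(groups_path) if groups_path else None
    return AbundanceTable(counts, taxonomy=taxonomy, sample_meta=meta)


def read_taxonomy(path) -> dict:
    frame = pd.read_csv(path, sep="\t", index_col=0, header=None,
                        names=["taxon", "lineage"])
    return frame["lineage"].to_dict()


def read_groups(path) -> dict:
    frame = pd.read_csv(path, sep="\t", index_col=0, header=None,
                        names=["sample", "group"])
    return frame["group"].to_dict()
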