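"""Second-order co-structuring statistics (the Spearman grid analysis).

The question is not whether gesture tracks voice in time, but whether
motif pairs that *sound* alike also *move* alike: for each of the 4 sonic
× 6 kinematic distance columns of the all-pairs DTW table, the Spearman
rank correlation between the two columns is computed.  Profiles are built
for the pooled performer set (motifs subsampled so every performer is
represented equally) and for each performer (pairs where both motifs are
that performer's).  Significance uses a Bonferroni-corrected α of
0.0001 / n_tests, n_tests = 24 cells × number of profiles (96 in the
canonical pooled + 3 performers design).

The randomization control (:func:`shuffle_null`) permutes each distance
column independently within each (performer_i, performer_j) stratum,
destroying pair-level coupling while preserving every column's per-stratum
marginal distribution.

Pairs sharing a motif are not independent; as in standard second-order
(representational-similarity / Mantel-style) analyses the p-values treat
rows as exchangeable, and a stricter motif-label permutation test is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .dtw import FEATURE_COLUMNS, KINEMATIC_FEATURES, SONIC_FEATURES

__all__ = [
    "CoStructureProfile",
    "spearman_grid",
    "equal_subsample",
    "shuffle_null",
    "bonferroni",
    "analyze_costructure",
    "profile_summary",
]

DEFAULT_ALPHA = 0.0001


@dataclass
class CoStructureProfile:
    """4×6 Spearman ρ / p grid for one performer set."""

    performer_set: str
    rho: pd.DataFrame          # index: sonic, columns: kinematic
    pval: pd.DataFrame
    n_pairs: int
    alpha: float = DEFAULT_ALPHA
    n_tests: int | None = None
    significant: pd.DataFrame | None = None

    @property
    def n_cells(self) -> int:
        return self.rho.size


def _pair_mask(table: pd.DataFrame, performer_set: str, motif_subset: set | None) -> pd.Series:
    if performer_set == "all":
        mask = pd.Series(True, index=table.index)
        if motif_subset is not None:
            mask &= table["motif_i"].isin(motif_subset) & table["motif_j"].isin(motif_subset)
        return mask
    return (table["performer_i"] == performer_set) & (table["performer_j"] == performer_set)


def spearman_grid(
    table: pd.DataFrame,
    performer_set: str = "all",
    motif_subset: set | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> CoStructureProfile:
    """Rank-correlate every sonic distance column with every kinematic one.

    ``performer_set`` is ``"all"`` (optionally restricted to an equal
    per-performer ``motif_subset``) or a performer id, in which case only
    pairs where *both* motifs belong to that performer are used.  Ties are
    handled by average ranks; p-values are two-sided.
    """
    sub = table[_pair_mask(table, performer_set, motif_subset)]
    if len(sub) < 3:
        raise ValueError(
            f"performer set {performer_set!r} has only {len(sub)} pairs; need >= 3"
        )
    rho = np.empty((len(SONIC_FEATURES), len(KINEMATIC_FEATURES)))
    pval = np.empty_like(rho)
    for i, sf in enumerate(SONIC_FEATURES):
        for j, kf in enumerate(KINEMATIC_FEATURES):
            res = spearmanr(sub[sf].to_numpy(), sub[kf].to_numpy())
            rho[i, j] = res.statistic
            pval[i, j] = res.pvalue
    return CoStructureProfile(
        performer_set=performer_set,
        rho=pd.DataFrame(rho, index=list(SONIC_FEATURES), columns=list(KINEMATIC_FEATURES)),
        pval=pd.DataFrame(pval, index=list(SONIC_FEATURES), columns=list(KINEMATIC_FEATURES)),
        n_pairs=len(sub),
        alpha=alpha,
    )


def equal_subsample(motif_table: pd.DataFrame, seed: int) -> list[str]:
    """Subsample motifs so each performer contributes equally.

    Every performer contributes exactly the minimum per-performer motif
    count, sampled without replacement under ``seed``.  Returns the
    retained motif ids in stable (input) order.
    """
    counts = motif_table.groupby("performer_id")["motif_id"].count()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("equal subsampling needs >= 2 performers, each with >= 1 motif")
    k = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: set[str] = set()
    for perf, grp in motif_table.groupby("performer_id", sort=True):
        ids = grp["motif_id"].tolist()
        chosen = rng.choice(len(ids), size=k, replace=False)
        keep.update(ids[c] for c in chosen)
    return [m for m in motif_table["motif_id"] if m in keep]


def shuffle_null(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Shuffle each distance column within features and performer sets.

    Every one of the 10 distance columns is permuted independently within
    each (performer_i, performer_j) stratum, so each column's per-stratum
    multiset of values — and all row metadata — is preserved while any
    pair-level association between columns is destroyed.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    key = [tuple(sorted(t)) for t in zip(table["performer_i"], table["performer_j"])]
    out["_stratum"] = pd.Series(key, index=out.index).astype(str)
    for col in FEATURE_COLUMNS:
        vals = out[col].to_numpy().copy()
        for _, idx in out.groupby("_stratum").indices.items():
            vals[idx] = vals[idx][rng.permutation(len(idx))]
        out[col] = vals
    return out.drop(columns="_stratum")


def bonferroni(profiles: list[CoStructureProfile], alpha: float = DEFAULT_ALPHA) -> list[CoStructureProfile]:
    """Mark per-cell significance at alpha / (total cells across profiles)."""
    n_tests = sum(p.n_cells for p in profiles)
    for p in profiles:
        p.alpha = alpha
        p.n_tests = n_tests
        p.significant = p.pval < (alpha / n_tests)
    return profiles


def analyze_costructure(
    table: pd.DataFrame,
    motif_table: pd.DataFrame,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    performer_sets: list[str] | None = None,
) -> list[CoStructureProfile]:
    """The full grid analysis: pooled (equally subsampled) + per performer.

    Returns Bonferroni-corrected profiles; with one pooled set and three
    performers the family has 96 tests.
    """
    performers = sorted(motif_table["performer_id"].unique())
    if performer_sets is None:
        performer_sets = ["all"] + performers
    profiles = []
    for ps in performer_sets:
        subset = set(equal_subsample(motif_table, seed)) if ps == "all" and len(performers) > 1 else None
        profiles.append(spearman_grid(table, ps, motif_subset=subset, alpha=alpha))
    return bonferroni(profiles, alpha)


def profile_summary(profiles: list[CoStructureProfile]) -> pd.DataFrame:
    """Long-format report: one row per (performer_set, sonic, kinematic) cell.

    Insignificant cells keep their ρ in the ``rho`` column but are masked
    (NaN) in ``rho_masked`` — the heatmap convention of graying out cells
    that fail the corrected threshold.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    rows = []
    for p in profiles:
        for sf in p.rho.index:
            for kf in p.rho.columns:
                sig = bool(p.significant.loc[sf, kf]) if p.significant is not None else False
                rows.append(
                    {
                        "performer_set": p.performer_set,
                        "sonic": sf,
                        "kinematic": kf,
                        "rho": p.rho.loc[sf, kf],
                        "pval": p.pval.loc[sf, kf],
                        "significant": sig,
                        "rho_masked": p.rho.loc[sf, kf] if sig else np.nan,
                        "n_pairs": p.n_pairs,
                    }
                )
    return pd.DataFrame(rows)
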