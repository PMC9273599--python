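"""Cancer-type-specific regional mutational density (RMD) profile extraction.

Per cancer-type cohort, the sample x bin RMD matrix is factorized by
KL-divergence NMF. The number of profiles (the NMF rank) is chosen by a
masked-imputation search: for each candidate rank, NMF runs repeatedly on
random sample subsets with a fraction of entries hidden, and the median
imputation error across runs is recorded; the chosen rank is the one before
the error starts increasing. Profiles from all classes are then deduplicated
by hierarchical clustering on Pearson correlation, and each sample's RMD
vector is fitted to the final profile set by non-negative least squares,
yielding the ``rmd.*`` features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from primarysite.nmf import NMFResult, impute_mse, nmf_kl

logger = logging.getLogger(__name__)

MASK_FRACTION = 0.1
RANK_SEARCH_SUBSET = 100
RANK_SEARCH_RUNS = 50
RANK_SEARCH_MAX_RANK = 10
#: Relative increase of log10(median MSE) that stops the rank search.
RANK_STEP_THRESHOLD = 0.002
DEDUP_CUT_HEIGHT = 0.1


@dataclass
class RankSearchResult:
    """Median imputation MSE per rank and the chosen rank."""

    median_mse: pd.Series  # rank -> median MSE
    chosen_rank: int


@dataclass
class RMDProfileSet:
    """Final deduplicated non-negative profiles over the RMD bins.

    ``profiles`` is a profiles x bins DataFrame with names "rmd.<class>.<k>";
    ``provenance`` maps each retained profile to its cluster group and the
    profiles it absorbed.
    """

    profiles: pd.DataFrame
    provenance: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("profiles must be non-negative")
        if self.profiles.index.duplicated().any():
            raise ValueError("profile names must be unique")

    @property
    def names(self) -> list[str]:
        return list(self.profiles.index)


def select_rank(
    V_class: np.ndarray,
    seed: int = 0,
    n_runs: int = RANK_SEARCH_RUNS,
    max_rank: int = RANK_SEARCH_MAX_RANK,
    subset_size: int = RANK_SEARCH_SUBSET,
    mask_fraction: float = MASK_FRACTION,
    max_iter: int = 2000,
    tol: float = 1e-4,
) -> RankSearchResult:
    """Choose the NMF rank for one class cohort by masked imputation.

    For each rank r in 1..max_rank, ``n_runs`` NMF fits are performed, each
    on a fresh random subset of ``subset_size`` samples with 10% of entries
    hidden from the loss; the median across runs of the held-out MSE gives
    the rank's score. The chosen rank is the largest r reached before the
    relative increase of log10(median MSE) from one rank to the next first
    exceeds 0.2% (rank 1 if the very first step already increases).
    """
    V = np.asarray(V_class, dtype=float)
    n = V.shape[0]
    if n < 2:
        return RankSearchResult(
            median_mse=pd.Series(dtype=float), chosen_rank=1
        )
    rng = np.random.default_rng(seed)
    subset_size = min(subset_size, n)
    max_rank = min(max_rank, subset_size, V.shape[1])
    medians = {}
    for rank in range(1, max_rank + 1):
        errors = []
        for _ in range(n_runs):
            rows = rng.choice(n, size=subset_size, replace=False)
            sub = V[rows]
            if sub.sum() == 0:
                continue
            mask = rng.random(sub.shape) >= mask_fraction
            # guard: a sample fully masked out would be unconstrained
            for i in np.flatnonzero(~mask.any(axis=1)):
                mask[i, rng.integers(sub.shape[1])] = True
            result = nmf_kl(sub, rank, mask=mask, max_iter=max_iter, tol=tol, seed=rng)
            errors.append(impute_mse(sub, result, mask))
        if not errors:
            raise ValueError("class RMD matrix is all zero")
        medians[rank] = float(np.median(errors))
    median_mse = pd.Series(medians)
    chosen = 1
    log_prev = np.log10(max(median_mse[1], 1e-300))
    for rank in range(2, max_rank + 1):
        log_cur = np.log10(max(median_mse[rank], 1e-300))
        rel = (log_cur - log_prev) / max(abs(log_prev), 1e-12)
        if rel > RANK_STEP_THRESHOLD:
            break
        chosen = rank
        log_prev = log_cur
    return RankSearchResult(median_mse=median_mse, chosen_rank=chosen)


def extract_profiles_per_class(
    rmd: pd.DataFrame,
    class_labels: pd.Series,
    seed: int = 0,
    rank_overrides: dict[str, int] | None = None,
    **rank_search_kwargs,
) -> dict[str, pd.DataFrame]:
    """Extract per-class profile matrices (rows L1-normalized).

    For each class, the rank is chosen by :func:`select_rank` (unless
    overridden) and a full unmasked NMF at that rank on all class samples
    yields the class's profiles, named "rmd.<class>.<k>".
    """
    labels = pd.Series(class_labels).reindex(rmd.index)
    if labels.isna().any():
        raise ValueError("class labels missing for some samples")
    out: dict[str, pd.DataFrame] = {}
    for i, cls in enumerate(sorted(labels.unique())):
        V = rmd.loc[labels == cls].to_numpy(dtype=float)
        cls_seed = _derive_seed(seed, i)
        if V.shape[0] == 1:
            H = V.copy()
            rank = 1
        else:
            if rank_overrides and cls in rank_overrides:
                rank = rank_overrides[cls]
            else:
                rank = select_rank(V, seed=cls_seed, **rank_search_kwargs).chosen_rank
            result = nmf_kl(V, rank, seed=cls_seed)
            H = result.H
        row_sums = H.sum(axis=1, keepdims=True)
        keep = row_sums[:, 0] > 0
        H = H[keep] / row_sums[keep]
        out[cls] = pd.DataFrame(
            H,
            index=[f"rmd.{cls}.{k + 1}" for k in range(H.shape[0])],
            columns=rmd.columns,
        )
    return out


def _derive_seed(seed: int, offset: int) -> int:
    return (seed * 100003 + offset * 7919 + 1) % (2**31 - 1)


def deduplicate_profiles(
    class_profiles: dict[str, pd.DataFrame],
    class_sizes: dict[str, int] | None = None,
    cut_height: float = DEDUP_CUT_HEIGHT,
) -> RMDProfileSet:
    """Merge near-identical profiles across classes into a final set.

    Profiles are clustered hierarchically (complete linkage) on the distance
    1 - Pearson correlation across bins; the dendrogram is cut at
    ``cut_height`` and one representative is kept per group: the profile from
    the class with the most training samples, ties broken by name. Profiles
    with zero variance across bins cannot be correlated and are excluded with
    a warning.
    """
    frames = [df for df in class_profiles.values() if len(df)]
    if not frames:
        raise ValueError("no profiles to deduplicate")
    all_profiles = pd.concat(frames)
    arr = all_profiles.to_numpy(dtype=float)
    # tolerance absorbs rounding noise in nominally constant rows
    variable = arr.std(axis=1) > 1e-12
    for name in all_profiles.index[~variable]:
        logger.warning("profile %s has zero variance across bins; excluded", name)
    all_profiles = all_profiles[variable]
    if all_profiles.empty:
        raise ValueError("all profiles have zero variance; nothing to deduplicate")
    arr = all_profiles.to_numpy(dtype=float)
    if arr.shape[0] == 1:
        groups = np.array([1])
    else:
        corr = np.corrcoef(arr)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        Z = linkage(condensed, method="complete")
        groups = fcluster(Z, t=cut_height, criterion="distance")

    if class_sizes is None:
        class_sizes = {}
    names = list(all_profiles.index)
    rows = []
    keep: list[str] = []
    for g in np.unique(groups):
        members = [names[i] for i in np.flatnonzero(groups == g)]
        rep = min(
            members,
            key=lambda nm: (-class_sizes.get(_profile_class(nm), 0), nm),
        )
        keep.append(rep)
        for nm in members:
            rows.append((nm, _profile_class(nm), int(g), rep, nm == rep))
    keep = [nm for nm in names if nm in set(keep)]  # stable order
    provenance = pd.DataFrame(
        rows, columns=["profile", "source_class", "group", "representative", "retained"]
    )
    return RMDProfileSet(profiles=all_profiles.loc[keep], provenance=provenance)


def _profile_class(name: str) -> str:
    parts = name.split(".")
    return parts[1] if len(parts) >= 3 else name


def fit_profile_contributions(
    rmd_vector: np.ndarray, profile_set: RMDProfileSet
) -> pd.Series:
    """Non-negative least-squares fit of one sample's RMD vector to the profiles."""
    v = np.asarray(rmd_vector, dtype=float)
    H = profile_set.profiles.to_numpy(dtype=float)
    if v.shape[0] != H.shape[1]:
        raise ValueError(
            f"RMD vector length {v.shape[0]} does not match profile bins {H.shape[1]}"
        )
    coef, _ = nnls(H.T, v)
    return pd.Series(coef, index=profile_set.names)


def fit_profile_matrix(rmd: pd.DataFrame, profile_set: RMDProfileSet) -> pd.DataFrame:
    """Profile contributions for every row of a samples x bins RMD matrix."""
    rows = {
        sid: fit_profile_contributions(rmd.loc[sid].to_numpy(), profile_set)
        for sid in rmd.index
    }
    return pd.DataFrame.from_dict(rows, orient="index").loc[rmd.index]
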