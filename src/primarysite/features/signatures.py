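"""Mutational-signature exposure fitting by non-negative least squares.

Context count vectors are fitted against a catalog of signature spectra
(columns are probability distributions over contexts). Child signatures that
represent variants of one mutational process are summed into their parent
(e.g. the UV-light signatures SBS7a-d into SBS7), and exposures are normalized
by the total mutational load of the corresponding mutation class so that
samples with very different burdens are comparable.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from primarysite.features.contexts import SCHEMES

#: Default parent <- children merge rules for COSMIC-style SBS catalogs.
DEFAULT_MERGE_MAP: Mapping[str, tuple[str, ...]] = {
    "SBS7": ("SBS7a", "SBS7b", "SBS7c", "SBS7d"),
    "SBS10": ("SBS10a", "SBS10b", "SBS10c", "SBS10d"),
    "SBS17": ("SBS17a", "SBS17b"),
}


def merge_child_signatures(
    exposures: pd.Series, merge_map: Mapping[str, tuple[str, ...]] | None = None
) -> pd.Series:
    """Sum child-signature exposures into their parent signature.

    Children absent from ``exposures`` are ignored; parents with no children
    present are left untouched. Column order is preserved, with the parent
    taking the position of its first child.
    """
    if merge_map is None:
        merge_map = DEFAULT_MERGE_MAP
    child_to_parent = {c: p for p, cs in merge_map.items() for c in cs}
    out: dict[str, float] = {}
    for name, value in exposures.items():
        target = child_to_parent.get(name, name)
        out[target] = out.get(target, 0.0) + float(value)
    return pd.Series(out)


def fit_signature_exposures(
    context_counts: pd.Series,
    signature_catalog: pd.DataFrame,
    merge_map: Mapping[str, tuple[str, ...]] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Fit context counts to a signature catalog by NNLS.

    Parameters
    ----------
    context_counts
        Non-negative counts indexed by context category.
    signature_catalog
        Contexts x signatures matrix; each column is non-negative and sums
        to 1 (a spectrum).
    merge_map
        Parent -> children merge rules applied to the fitted exposures;
        defaults to the SBS7/SBS10/SBS17 family merges.

    Returns
    -------
    (exposures, normalized)
        ``exposures`` are the merged NNLS coefficients (mutation counts
        attributed to each signature); ``normalized`` divides by the total
        mutation count of the class (all zero when the count is zero).
    """
    counts = np.asarray(context_counts, dtype=float)
    if counts.ndim != 1 or len(counts) != signature_catalog.shape[0]:
        raise ValueError(
            f"counts length {counts.shape} does not match catalog rows "
            f"{signature_catalog.shape[0]}"
        )
    if (counts < 0).any():
        raise ValueError("context counts must be non-negative")
    A = signature_catalog.to_numpy(dtype=float)
    if (A < 0).any():
        raise ValueError("signature catalog must be non-negative")
    col_sums = A.sum(axis=0)
    if not np.allclose(col_sums[col_sums > 0], 1.0, atol=1e-6):
        raise ValueError("signature catalog columns must each sum to 1")
    coef, _ = nnls(A, counts)
    exposures = merge_child_signatures(
        pd.Series(coef, index=signature_catalog.columns), merge_map
    )
    total = counts.sum()
    normalized = exposures / total if total > 0 else exposures * 0.0
    return exposures, normalized


def synthetic_catalog(scheme: str, n_signatures: int = 8, seed: int = 0) -> pd.DataFrame:
    """Build a synthetic signature catalog with sparse, well-separated spectra.

    This is a stand-in reference catalog for testing and simulation, not a
    real mutational-process catalog: each signature concentrates mass on its
    own subset of contexts (plus a small uniform floor) so that mixtures are
    identifiable. Signatures are named by scheme prefix (SBS1..; the first
    SBS names include child signatures 7a/7b so the merge path is exercised).
    """
    contexts = SCHEMES[scheme]
    rng = np.random.default_rng(seed)
    n_ctx = len(contexts)
    cols = {}
    names = _synthetic_names(scheme, n_signatures)
    blocks = np.array_split(rng.permutation(n_ctx), n_signatures)
    for name, block in zip(names, blocks):
        spectrum = np.full(n_ctx, 0.02 / n_ctx)
        spectrum[block] += rng.dirichlet(np.ones(len(block))) * 0.98
        cols[name] = spectrum / spectrum.sum()
    return pd.DataFrame(cols, index=list(contexts))


def _synthetic_names(scheme: str, n: int) -> list[str]:
    prefix = {"SBS96": "SBS", "DBS78": "DBS", "ID83": "ID"}[scheme]
    names = [f"{prefix}{i}" for i in range(1, n + 1)]
    if prefix == "SBS" and n >= 8:
        # use two child signatures of SBS7 so merge rules have work to do
        names[6] = "SBS7a"
        names[7] = "SBS7b"
    return names
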