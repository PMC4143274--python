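"""A single white-matter "integrity" score from the tensor eigenvalues.

Per-subject mean NAWM eigenvalues (lambda1, lambda2, lambda3) are highly
collinear; the first principal component of the z-scored columns collapses
them into one factor. Sign convention: the score is oriented to correlate
positively with mean diffusivity, i.e. HIGHER score = MORE diffusivity =
WORSE microstructural integrity. The name "NAWM integrity" therefore pairs
with NEGATIVE expected paths to cognition; this is deliberate and matters
when reading coefficient signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["IntegrityFactor", "integrity_scores", "DEFAULT_EIGENVALUE_COLUMNS"]

DEFAULT_EIGENVALUE_COLUMNS = ("nawm_l1", "nawm_l2", "nawm_l3")


@dataclass
class IntegrityFactor:
    loadings: np.ndarray  # unit-norm weights on the z-scored eigenvalue columns
    explained_variance_fraction: float
    scores: pd.Series  # standardized (mean 0, SD 1) over included subjects
    excluded: pd.Index  # subjects dropped for missing eigenvalues


def integrity_scores(
    cohort: pd.DataFrame, columns: tuple[str, str, str] = DEFAULT_EIGENVALUE_COLUMNS
) -> IntegrityFactor:
    """First principal component of the z-scored eigenvalue columns."""
    cols = list(columns)
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table lacks eigenvalue columns {missing}")
    x = cohort[cols]
    complete = x.notna().all(axis=1)
    excluded = cohort.index[~complete]
    x = x.loc[complete].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects with complete eigenvalues")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("zero-variance eigenvalue column; factor undefined")
    z = (x - x.mean(axis=0)) / sd

    pca = PCA(n_components=1).fit(z)
    loadings = pca.components_[0]
    loadings = loadings / np.linalg.norm(loadings)
    raw = z @ loadings
    # orient: higher score = higher mean diffusivity
    if np.corrcoef(raw, x.mean(axis=1))[0, 1] < 0:
        loadings = -loadings
        raw = -raw
    scores = (raw - raw.mean()) / raw.std(ddof=1)
    return IntegrityFactor(
        loadings=loadings,
        explained_variance_fraction=float(pca.explained_variance_ratio_[0]),
        scores=pd.Series(scores, index=cohort.index[complete], name="nawm_integrity"),
        excluded=excluded,
    )
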