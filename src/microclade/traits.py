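"""Y-A-S trait projection of clade composition and PCA of the profiles.

Each of the 12 clades carries a row-stochastic vector of relative abundances
over eight genome-based trait categories (growth Yield: amino acid-related
enzymes, lipid biosynthesis, lipopolysaccharide biosynthesis; resource
Acquisition: CAZymes, polycyclic aromatic hydrocarbon degradation; Stress
tolerance: chaperones/folding catalysts, peptidoglycan biosynthesis and
degradation, prokaryotic defense systems). A sample's functional profile is
the clade-abundance-weighted average of those rows — a matrix product that
maps the clade simplex onto the trait simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import assert_abundance_table
from .labels import MAIN_CLADES
from .stats import PermanovaResult, bray_curtis, euclidean, permanova

ROW_SUM_TOL = 1e-9


def project_traits(clade_abund: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Samples x traits profile: profile = clade_abund @ traits.

    ``clade_abund`` must be restricted to the 12 main clades (pseudo clades
    carry no trait information) with rows on the simplex; ``traits`` must be
    row-stochastic, so profiles land on the trait simplex.
    """
    missing = [c for c in clade_abund.columns if c not in traits.index]
    if missing:
        raise KeyError(f"trait matrix lacks clades: {missing}")
    extra = [c for c in clade_abund.columns if c not in MAIN_CLADES]
    if extra:
        raise ValueError(f"abundance table must contain only main clades, found: {extra}")
    assert_abundance_table(clade_abund)
    t = traits.loc[list(clade_abund.columns)]
    bad = np.abs(t.sum(axis=1) - 1.0) > ROW_SUM_TOL
    if bad.any():
        raise ValueError(f"trait rows must sum to 1: clades {list(t.index[bad])}")
    profile = clade_abund.to_numpy() @ t.to_numpy()
    return pd.DataFrame(profile, index=clade_abund.index, columns=t.columns)


@dataclass(frozen=True)
class PcaResult:
    """PCA of functional profiles.

    ``loadings`` are factor loadings in the classical sense: the Pearson
    correlation between each component's scores and each original trait
    column (undefined — NaN — for constant columns, listed in
    ``constant_columns``). ``components`` are the orthonormal right singular
    vectors, kept so the centered data can be reconstructed exactly.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray  # variances along components (n-1 denominator)
    proportion_explained: np.ndarray
    loadings: pd.DataFrame
    components: pd.DataFrame
    mean: pd.Series
    constant_columns: tuple[str, ...]


def pca_profiles(profiles: pd.DataFrame, scale: bool = False) -> PcaResult:
    """PCA of samples x traits profiles (mean-centered, unscaled by default).

    ``scale=True`` divides each column by its standard deviation first
    (correlation-matrix PCA); the default mirrors the convention of centering
    only, appropriate when all columns share the proportion scale.
    """
    if len(profiles) < 3:
        raise ValueError(f"PCA needs at least 3 samples, got {len(profiles)}")
    x = profiles.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    centered = x - mean
    sd = centered.std(axis=0, ddof=1)
    constant = sd <= 1e-12
    if scale:
        centered = centered / np.where(constant, 1.0, sd)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    n = len(profiles)
    variances = (s**2) / (n - 1)
    comp_names = [f"PC{i+1}" for i in range(len(s))]
    scores_df = pd.DataFrame(scores, index=profiles.index, columns=comp_names)
    # factor loadings: corr(score_k, trait_j); NaN where the trait is constant
    loadings = np.full((profiles.shape[1], len(s)), np.nan)
    score_sd = scores.std(axis=0, ddof=1)
    for j in range(profiles.shape[1]):
        if constant[j]:
            continue
        xc = x[:, j] - mean[j]
        for k in range(len(s)):
            if score_sd[k] <= 1e-12:
                loadings[j, k] = np.nan
            else:
                loadings[j, k] = float(
                    (xc * (scores[:, k] - scores[:, k].mean())).sum()
                    / ((n - 1) * sd[j] * score_sd[k])
                )
    total_var = variances.sum()
    return PcaResult(
        scores=scores_df,
        eigenvalues=variances,
        proportion_explained=variances / total_var if total_var > 0 else variances,
        loadings=pd.DataFrame(loadings, index=profiles.columns, columns=comp_names),
        components=pd.DataFrame(vt.T, index=profiles.columns, columns=comp_names),
        mean=pd.Series(mean, index=profiles.columns),
        constant_columns=tuple(profiles.columns[constant]),
    )


def permanova_on_profiles(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: tuple[str, ...] = ("site", "inoculum", "site:inoculum"),
    n_permutations: int = 999,
    seed: int = 1,
    metric: str = "euclidean",
) -> PermanovaResult:
    """PERMANOVA of functional profiles (Euclidean by default).

    Profiles are proportions on a common scale, so Euclidean distance is the
    natural choice and gives the characteristically tiny sums of squares;
    ``metric="braycurtis"`` is exposed for symmetry with the clade analysis.
    """
    if metric == "euclidean":
        dm = euclidean(profiles)
    elif metric == "braycurtis":
        dm = bray_curtis(profiles)
    else:
        raise ValueError(f"metric must be 'euclidean' or 'braycurtis', got {metric!r}")
    return permanova(
        dm, metadata, terms=terms, n_permutations=n_permutations, seed=seed
    )
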