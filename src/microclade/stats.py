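"""Distance-based multivariate statistics: Bray-Curtis, PCoA, PERMANOVA, PERMDISP.

All four are implemented directly on the distance matrix.

* Bray-Curtis dissimilarity ``D(i,j) = sum|x_i - x_j| / sum(x_i + x_j)``.
* Principal coordinate analysis via Gower double-centering
  ``G = -1/2 J (D o D) J`` and eigendecomposition; negative eigenvalues are
  reported, not corrected.
* PERMANOVA partitions ``SS_total = tr(G)`` by sequential (Type-I) hat-matrix
  projections of the cumulative model matrices (the McArdle-Anderson
  identity ``SS_k = tr(H_k G) - tr(H_{k-1} G)``), with pseudo-F tested
  against free permutation of the samples.
* PERMDISP embeds the samples (keeping real and imaginary axes separately),
  measures each sample's distance to its group centroid as
  ``sqrt(d+^2 - d-^2)`` and applies a one-way permutation F test to those
  distances.

Permutation p-values use the +1 correction ``(1 + #{F* >= F}) / (1 + n_perm)``
with ties counted as extreme. Samples are put in a canonical sorted order
before any permutation is drawn, so p-values do not depend on input row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

EPS = 1e-12
_CHUNK = 250  # permuted-Gower chunk size, bounds peak memory


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max(initial=0.0) > 1e-10:
            raise ValueError("distance matrix must have a zero diagonal")
        object.__setattr__(self, "data", d)

    def __len__(self) -> int:
        return len(self.ids)

    def reorder(self, ids) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(tuple(ids), self.data[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between the rows of an abundance table."""
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=-1)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=-1)
    both_zero = den <= 0
    if both_zero.any() and (both_zero & ~np.eye(len(x), dtype=bool)).any():
        i, j = np.argwhere(both_zero & ~np.eye(len(x), dtype=bool))[0]
        raise ValueError(
            f"Bray-Curtis undefined for all-zero pair ({table.index[i]}, {table.index[j]})"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(both_zero, 0.0, num / np.where(both_zero, 1.0, den))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(map(str, table.index)), (d + d.T) / 2.0)


def euclidean(table: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between the rows of a feature table."""
    x = table.to_numpy(dtype=float)
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1)
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(map(str, table.index)), (d + d.T) / 2.0)


def _gower(d: np.ndarray) -> np.ndarray:
    """Double-centered -1/2 D^2 matrix whose trace is the total SS."""
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrdinationResult:
    """Metric embedding of a distance matrix.

    ``coordinates`` hold the positive-eigenvalue axes (PCo1, PCo2, ...).
    ``negative_coordinates`` hold the imaginary part of a non-Euclidean
    embedding (axes scaled by sqrt(-eigenvalue)); they carry no plotting
    meaning but are required to compute exact distances to centroids.
    ``proportion_explained`` is over the positive eigenvalue sum.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_coordinates: pd.DataFrame


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (no negative-eigenvalue correction)."""
    n = len(dm)
    if n < 3:
        raise ValueError(f"PCoA needs at least 3 samples, got {n}")
    g = _gower(dm.data)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), abs(eigval[-1]), 1.0) * 1e-10
    pos = eigval > tol
    neg = eigval < -tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    neg_coords = eigvec[:, neg] * np.sqrt(-eigval[neg])
    ids = list(dm.ids)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PCo{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=eigval,
        proportion_explained=eigval[pos] / eigval[pos].sum() if pos.any() else np.array([]),
        negative_coordinates=pd.DataFrame(
            neg_coords, index=ids, columns=[f"nPCo{i+1}" for i in range(neg_coords.shape[1])]
        ),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermResult:
    name: str
    df: int
    ss: float
    r2: float
    f: float
    p: float


@dataclass(frozen=True)
class PermanovaResult:
    terms: tuple[TermResult, ...]
    residual_df: int
    residual_ss: float
    residual_r2: float
    total_ss: float
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "Df": t.df, "SS": t.ss, "R2": t.r2, "F": t.f, "p": t.p}
            for t in self.terms
        ]
        rows.append(
            {
                "term": "Residual",
                "Df": self.residual_df,
                "SS": self.residual_ss,
                "R2": self.residual_r2,
                "F": float("nan"),
                "p": float("nan"),
            }
        )
        rows.append(
            {
                "term": "Total",
                "Df": self.residual_df + sum(t.df for t in self.terms),
                "SS": self.total_ss,
                "R2": 1.0,
                "F": float("nan"),
                "p": float("nan"),
            }
        )
        return pd.DataFrame(rows).set_index("term")


def _one_hot(values: pd.Series) -> np.ndarray:
    levels = pd.unique(values.astype(str))
    if len(levels) < 2:
        raise ValueError(f"factor {values.name!r} needs >= 2 levels")
    return (values.astype(str).to_numpy()[:, None] == levels[None, :]).astype(float)


def _term_matrix(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy coding of a main effect ``a`` or interaction ``a:b``."""
    blocks = []
    for factor in term.split(":"):
        factor = factor.strip()
        if factor not in metadata.columns:
            raise KeyError(f"metadata lacks factor {factor!r} (term {term!r})")
        blocks.append(_one_hot(metadata[factor]))
    x = blocks[0]
    for b in blocks[1:]:
        x = np.einsum("ij,ik->ijk", x, b).reshape(len(x), -1)
    return x


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(x) and its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s[0] * max(x.shape) * np.finfo(float).eps if s.size else 0.0
    r = int((s > tol).sum())
    basis = u[:, :r]
    return basis @ basis.T, r


def _permutation_stack(g: np.ndarray, perms: np.ndarray, hats: list[np.ndarray]):
    """tr(H_k G_pi) for every permutation pi and cumulative hat H_k."""
    out = np.empty((len(hats), len(perms)))
    for start in range(0, len(perms), _CHUNK):
        chunk = perms[start : start + _CHUNK]
        gp = g[chunk[:, :, None], chunk[:, None, :]]
        for k, h in enumerate(hats):
            out[k, start : start + len(chunk)] = np.einsum("pij,ij->p", gp, h)
    return out


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: tuple[str, ...] = ("site", "inoculum", "site:inoculum"),
    n_permutations: int = 999,
    seed: int = 1,
    method: str = "monte-carlo",
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (Type-I) SS.

    Terms are fitted in the order given; for the default crossed transplant
    design this is site, inoculum, site:inoculum, matching the convention in
    which the R-squared values of the terms and the residual sum to one.
    ``method="exact"`` enumerates all n! sample permutations (n <= 9) and
    reports the exact tail fraction; otherwise ``n_permutations`` free
    permutations are drawn and the +1-corrected p is reported.
    """
    ids = sorted(dm.ids)
    dm = dm.reorder(ids)
    missing = [s for s in ids if s not in metadata.index]
    if missing:
        raise KeyError(f"metadata lacks samples: {missing[:5]}")
    md = metadata.loc[ids]
    n = len(ids)
    g = _gower(dm.data)
    total_ss = float(np.trace(g))

    hats: list[np.ndarray] = []
    dfs: list[int] = []
    x = np.ones((n, 1))
    h_prev, rank_prev = _hat(x)
    for term in terms:
        x = np.hstack([x, _term_matrix(md, term)])
        h, rank = _hat(x)
        df = rank - rank_prev
        if df <= 0:
            raise ValueError(f"term {term!r} is confounded with earlier terms (0 df)")
        hats.append(h)
        dfs.append(df)
        h_prev, rank_prev = h, rank
    residual_df = n - rank_prev
    if residual_df <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    def f_from_traces(traces, tr_g):
        # traces: (n_terms,) or (n_terms, n_perm); cumulative tr(H_k G)
        traces = np.asarray(traces, dtype=float)
        prev = np.zeros_like(traces[0])
        ss_terms = []
        for k in range(len(hats)):
            ss_terms.append(traces[k] - prev)
            prev = traces[k]
        ss_res = tr_g - traces[-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            fs = [
                (ss_terms[k] / dfs[k]) / (ss_res / residual_df)
                for k in range(len(hats))
            ]
        return np.asarray(ss_terms), ss_res, np.asarray(fs)

    obs_traces = np.array([float(np.sum(h * g)) for h in hats])
    ss_terms, ss_res, f_obs = f_from_traces(obs_traces, total_ss)

    if method == "exact":
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9 samples")
        perms = np.array(list(iter_permutations(range(n))))
        n_perm = len(perms)
        traces = _permutation_stack(g, perms, hats)
        _, _, f_perm = f_from_traces(traces, total_ss)
        p_values = (f_perm >= f_obs[:, None] - EPS).mean(axis=1)
    elif method == "monte-carlo":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EA]))
        n_perm = int(n_permutations)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        traces = _permutation_stack(g, perms, hats)
        _, _, f_perm = f_from_traces(traces, total_ss)
        exceed = (f_perm >= f_obs[:, None] - EPS).sum(axis=1)
        p_values = (1.0 + exceed) / (1.0 + n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")

    r2_of = lambda ss: float(ss / total_ss) if abs(total_ss) > EPS else float("nan")
    results = tuple(
        TermResult(
            name=terms[k],
            df=dfs[k],
            ss=float(ss_terms[k]),
            r2=r2_of(ss_terms[k]),
            f=float(f_obs[k]),
            p=float(p_values[k]),
        )
        for k in range(len(terms))
    )
    return PermanovaResult(
        terms=results,
        residual_df=residual_df,
        residual_ss=float(ss_res),
        residual_r2=r2_of(ss_res),
        total_ss=total_ss,
        n_permutations=n_perm,
        seed=seed if method == "monte-carlo" else None,
    )


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermdispResult:
    distances: pd.Series  # per-sample distance to its group centroid
    f: float
    p: float
    df: int
    ss_between: float
    r2: float
    n_permutations: int
    seed: int


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """One-way ANOVA F plus between-group SS on a vector of distances."""
    n = len(values)
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for gidx in range(n_groups):
        member = values[codes == gidx]
        ssb += len(member) * (member.mean() - grand) ** 2
        ssw += ((member - member.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    f = (ssb / df_b) / (ssw / df_w) if ssw > EPS else math.inf if ssb > EPS else 0.0
    return f, ssb, ssw


def _spatial_median(points: np.ndarray, n_iter: int = 200, tol: float = 1e-10):
    """Weiszfeld iteration for the geometric median."""
    m = points.mean(axis=0)
    for _ in range(n_iter):
        d = np.linalg.norm(points - m, axis=1)
        if (d < tol).any():
            return points[d < tol][0]
        w = 1.0 / d
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def permdisp(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int = 1,
    center: str = "centroid",
) -> PermdispResult:
    """Homogeneity of multivariate dispersions (distance to group centroid).

    Samples are embedded with PCoA; the real and imaginary sub-embeddings are
    kept separately and a sample's distance to its group centre is
    ``sqrt(max(0, d+^2 - d-^2))``, exact for any symmetric dissimilarity.
    ``center="centroid"`` (default) uses the group mean; ``"median"`` the
    geometric (spatial) median. The F statistic on those distances is tested
    by permuting group labels.
    """
    ids = sorted(dm.ids)
    dm = dm.reorder(ids)
    grp = groups.reindex(ids)
    if grp.isna().any():
        raise KeyError(f"groups lack samples: {list(grp.index[grp.isna()])[:5]}")
    levels = pd.unique(grp.astype(str))
    codes = pd.Categorical(grp.astype(str), categories=levels).codes.astype(int)
    sizes = np.bincount(codes, minlength=len(levels))
    if (sizes < 2).any():
        bad = [levels[i] for i in np.where(sizes < 2)[0]]
        raise ValueError(f"singleton group(s): {bad}")

    ord_res = pcoa(dm)
    pos = ord_res.coordinates.to_numpy()
    neg = ord_res.negative_coordinates.to_numpy()
    dist = np.empty(len(ids))
    for gidx in range(len(levels)):
        member = codes == gidx
        if center == "centroid":
            c_pos = pos[member].mean(axis=0)
            c_neg = neg[member].mean(axis=0) if neg.size else np.zeros(0)
        elif center == "median":
            c_pos = _spatial_median(pos[member])
            c_neg = _spatial_median(neg[member]) if neg.size else np.zeros(0)
        else:
            raise ValueError(f"center must be 'centroid' or 'median', got {center!r}")
        d_pos = ((pos[member] - c_pos) ** 2).sum(axis=1)
        d_neg = ((neg[member] - c_neg) ** 2).sum(axis=1) if neg.size else 0.0
        dist[member] = np.sqrt(np.maximum(d_pos - d_neg, 0.0))

    f_obs, ssb, ssw = _anova_f(dist, codes, len(levels))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD15B]))
    exceed = 0
    for _ in range(int(n_permutations)):
        f_perm, _, _ = _anova_f(dist[rng.permutation(len(dist))], codes, len(levels))
        if f_perm >= f_obs - EPS:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermdispResult(
        distances=pd.Series(dist, index=ids, name="distance_to_centroid"),
        f=float(f_obs),
        p=float(p),
        df=len(levels) - 1,
        ss_between=float(ssb),
        r2=float(ssb / (ssb + ssw)) if (ssb + ssw) > EPS else 0.0,
        n_permutations=int(n_permutations),
        seed=seed,
    )
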