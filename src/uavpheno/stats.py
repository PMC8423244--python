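"""Nonparametric trait statistics.

Agronomic trait tables from small field trials (three replicates per
genotype) rarely pass normality screens, so the analysis layer is
rank-based throughout:

* Shapiro-Wilk W per trait as a reported gate (the pipeline proceeds
  nonparametrically regardless of its outcome);
* Kruskal-Wallis rank-sum test per trait, tie-corrected,
  H = [12/(N(N+1))] Σ R_i²/n_i − 3(N+1), divided by
  1 − Σ(t³−t)/(N³−N), with a chi-square tail on g−1 df;
* Dunn's post hoc z for each pair,
  z_ij = (r̄_i − r̄_j) / sqrt([N(N+1)/12 − Σ(t³−t)/(12(N−1))](1/n_i + 1/n_j)),
  two-sided normal p, Bonferroni-adjusted over all g(g−1)/2 pairs;
* a compact letter display summarizing the adjusted pairwise pattern —
  groups share a letter iff they are not significantly different;
* Spearman correlation matrices (mid-rank Pearson, t approximation on
  n−2 df, pairwise-complete);
* PCA on the correlation matrix of standardized traits, optionally folding
  EXR to |EXR| first so its sign convention (red-emphasizing, hence
  anti-correlated with the green indices) does not dominate the loadings.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (DataIntegrityError, DegenerateInputError,
                     InsufficientDataError, InvalidParameterError)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- normality

def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk (W, p). Requires 3 <= n <= 5000 and non-constant data."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise InsufficientDataError(
            f"Shapiro-Wilk needs at least 3 observations, got {values.size}")
    if values.size > 5000:
        raise InsufficientDataError("Shapiro-Wilk supports at most 5000 observations")
    if np.ptp(values) == 0:
        raise DegenerateInputError("Shapiro-Wilk is undefined for constant samples")
    w, p = sps.shapiro(values)
    return float(w), float(p)


# ------------------------------------------------------------ rank helpers

def _ranked(groups: Sequence[np.ndarray]):
    """Mid-ranks of the pooled sample, split back per group, plus the tie term
    Σ(t³ − t) over tied value groups."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # average (mid) ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    split = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
    return split, tie_term, len(pooled)


def _as_groups(groups: Iterable) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise InvalidParameterError("need at least 2 groups")
    if any(g.size == 0 for g in out):
        raise InvalidParameterError("every group must be non-empty")
    return out


def kruskal_wallis(groups: Iterable) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis test. Returns (H, df, p).

    All-identical data is a valid degenerate case: H = 0, p = 1.
    """
    gs = _as_groups(groups)
    split, tie_term, n = _ranked(gs)
    h_raw = 12.0 / (n * (n + 1)) * sum(r.sum() ** 2 / r.size for r in split) \
        - 3.0 * (n + 1)
    correction = 1.0 - tie_term / (n ** 3 - n)
    df = len(gs) - 1
    if correction <= 0:  # every pooled value identical
        return 0.0, df, 1.0
    h = h_raw / correction
    h = max(h, 0.0)  # guard tiny negative rounding
    return float(h), df, float(sps.chi2.sf(h, df))


def dunn_bonferroni(groups: Iterable, labels: Sequence[str] | None = None
                    ) -> pd.DataFrame:
    """Dunn's pairwise post hoc after Kruskal-Wallis, Bonferroni-adjusted.

    Returns a table with one row per unordered pair:
    ``group_i, group_j, z, p_raw, p_adj, significant`` (at the adjusted 0.05
    level). z uses mean ranks of the pooled ranking with the tie-corrected
    variance.
    """
    gs = _as_groups(groups)
    g = len(gs)
    if labels is None:
        labels = [f"g{i}" for i in range(g)]
    if len(labels) != g:
        raise InvalidParameterError("labels length must match number of groups")
    split, tie_term, n = _ranked(gs)
    mean_ranks = np.array([r.mean() for r in split])
    sizes = np.array([r.size for r in split], dtype=float)
    var_term = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    n_pairs = g * (g - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(g), 2):
        se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * n_pairs)
        rows.append({"group_i": labels[i], "group_j": labels[j], "z": float(z),
                     "p_raw": p_raw, "p_adj": p_adj})
    table = pd.DataFrame(rows)
    table["significant"] = table["p_adj"] < 0.05
    return table


# ------------------------------------------------------ compact letter display

def _letter(i: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ..."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def compact_letters(significant: Mapping[tuple[str, str], bool],
                    group_order: Sequence[str]) -> dict[str, str]:
    """Letter display for a symmetric, irreflexive significance relation.

    Two groups share at least one letter iff their pair is *not*
    significant. Letters are the maximal cliques of the non-significance
    graph, ordered by their first member in ``group_order`` (then by
    membership) for determinism — the fixed point of the classic
    insert-and-absorb construction.
    """
    sig: dict[frozenset, bool] = {}
    for (a, b), s in significant.items():
        if a == b:
            raise DataIntegrityError(f"significance relation must be irreflexive: ({a},{a})")
        key = frozenset((a, b))
        if key in sig and sig[key] != bool(s):
            raise DataIntegrityError(f"asymmetric significance relation for pair ({a},{b})")
        sig[key] = bool(s)
    order = {name: i for i, name in enumerate(group_order)}
    missing = [p for p in itertools.combinations(group_order, 2)
               if frozenset(p) not in sig]
    if missing:
        raise DataIntegrityError(f"significance relation missing pairs: {missing[:5]}")

    graph = nx.Graph()
    graph.add_nodes_from(group_order)
    for pair, s in sig.items():
        if not s:
            a, b = tuple(pair)
            graph.add_edge(a, b)
    cliques = [tuple(sorted(c, key=order.__getitem__)) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: [order[m] for m in c])
    letters: dict[str, list[str]] = {name: [] for name in group_order}
    for i, clique in enumerate(cliques):
        for member in clique:
            letters[member].append(_letter(i))
    return {name: "".join(sorted(ls)) for name, ls in letters.items()}


@dataclass
class RankTestResult:
    """Kruskal-Wallis + Dunn letters for one trait within one set."""

    trait: str
    set_id: int
    h: float
    df: int
    p: float
    group_letters: dict[str, str] = field(default_factory=dict)


# ------------------------------------------------------------- correlations

@dataclass
class CorrelationMatrix:
    set_id: int
    traits: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def spearman_pair(x, y) -> tuple[float, float, int]:
    """Spearman rho of one complete-case pair with the t approximation
    (n − 2 df). Returns (rho, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return np.nan, np.nan, n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0, n
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p, n


def spearman_matrix(table: pd.DataFrame, traits: Sequence[str],
                    set_id: int | None = None) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation matrix over trait columns.

    Zero-variance columns get NaN rows/columns (logged), never a crash.
    """
    df = table if set_id is None else table[table["set"] == set_id]
    traits = tuple(traits)
    k = len(traits)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    for i in range(k):
        col = df[traits[i]].to_numpy(dtype=float)
        finite = col[np.isfinite(col)]
        if finite.size and np.ptp(finite) == 0:
            logger.warning("spearman_matrix: column %r has zero variance", traits[i])
        rho[i, i] = 1.0
        pmat[i, i] = 0.0
        nmat[i, i] = int(np.isfinite(col).sum())
        for j in range(i + 1, k):
            r, p, n = spearman_pair(df[traits[i]], df[traits[j]])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
            nmat[i, j] = nmat[j, i] = n
    idx = list(traits)
    return CorrelationMatrix(set_id=set_id if set_id is not None else -1,
                             traits=traits,
                             rho=pd.DataFrame(rho, index=idx, columns=idx),
                             p=pd.DataFrame(pmat, index=idx, columns=idx),
                             n=pd.DataFrame(nmat, index=idx, columns=idx))


# --------------------------------------------------------------------- PCA

@dataclass
class PCAResult:
    variables: tuple[str, ...]
    loadings: pd.DataFrame      # variables x components (orthonormal columns)
    explained_pct: np.ndarray   # per component, sums to 100
    scores: np.ndarray          # observations x components
    n_obs: int


def pca_traits(table: pd.DataFrame, variables: Sequence[str],
               abs_exr: bool = True, use_correlation: bool = True) -> PCAResult:
    """PCA of trait columns via eigendecomposition of their correlation
    matrix (listwise-complete observations).

    ``abs_exr`` replaces the ``exr`` column with its absolute value before
    standardization. Constant variables are dropped with a warning.
    Component signs are fixed so each component's largest-magnitude loading
    is positive; explained percentages are 100 λ_j / Σλ, non-increasing.
    """
    variables = list(variables)
    data = table[variables].astype(float).copy()
    if abs_exr and "exr" in data.columns:
        data["exr"] = data["exr"].abs()
    data = data.dropna(axis=0, how="any")
    n_dropped = len(table) - len(data)
    if n_dropped:
        logger.info("pca_traits: dropped %d incomplete observation(s)", n_dropped)
    keep = [v for v in variables if np.ptp(data[v].to_numpy()) > 0]
    dropped = sorted(set(variables) - set(keep))
    if dropped:
        logger.warning("pca_traits: dropped constant variable(s) %s", dropped)
    if len(keep) < 2:
        raise InsufficientDataError("PCA needs at least 2 non-constant variables")
    if len(data) < 3:
        raise InsufficientDataError("PCA needs at least 3 complete observations")
    x = data[keep].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    if use_correlation:
        scale = x.std(axis=0, ddof=1)
        z = (x - mean) / scale
    else:
        z = x - mean
    cov = np.cov(z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    explained = 100.0 * eigvals / eigvals.sum()
    comp_names = [f"PC{j + 1}" for j in range(len(keep))]
    loadings = pd.DataFrame(eigvecs, index=keep, columns=comp_names)
    return PCAResult(variables=tuple(keep), loadings=loadings,
                     explained_pct=explained, scores=z @ eigvecs, n_obs=len(data))


# ------------------------------------------------------------ report layer

GROWTH_TRAITS = ("sur_cm2", "eph_mm", "sd_mm", "nn")
VI_TRAITS = ("exg", "exgr", "exr", "ndi", "gli", "vari")
ALL_TRAITS = GROWTH_TRAITS + VI_TRAITS


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """The conventional star code: *** <0.001, ** <0.01, * <alpha, else NS."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "NS"


def trait_stats_report(trait_table: pd.DataFrame, alpha: float = 0.05
                       ) -> dict[str, pd.DataFrame]:
    """The full statistical report for a two-set trait table.

    Produces, per set: Shapiro-Wilk screens, entry and replicate
    Kruskal-Wallis tests per trait, Dunn-Bonferroni pairwise tables with
    compact letters for traits whose entry effect is significant, Spearman
    matrices, and three PCAs (growth+VI, growth only, VI only; EXR folded to
    |EXR|). Returned as named DataFrames ready to serialize.
    """
    sets = sorted(trait_table["set"].unique())
    kw_rows, shapiro_rows, dunn_frames, letter_rows = [], [], [], []
    traits_present = [t for t in ALL_TRAITS
                      if t in trait_table.columns and trait_table[t].notna().any()]
    for set_id in sets:
        sub = trait_table[trait_table["set"] == set_id]
        for trait in traits_present:
            vals = sub[trait].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size >= 3 and np.ptp(finite) > 0:
                w, p_sw = shapiro_normality(finite)
            else:
                w, p_sw = np.nan, np.nan
            shapiro_rows.append({"set": set_id, "trait": trait, "W": w, "p": p_sw,
                                 "normal": significance_stars(p_sw, alpha) == "NS"
                                 if np.isfinite(p_sw) else None})
            for source in ("entry", "rep"):
                groups, labels = [], []
                for label, grp in sub.groupby(source):
                    g = grp[trait].to_numpy(dtype=float)
                    g = g[np.isfinite(g)]
                    if g.size:
                        groups.append(g)
                        labels.append(str(label))
                if len(groups) < 2:
                    continue
                h, df, p = kruskal_wallis(groups)
                kw_rows.append({"set": set_id, "trait": trait, "source": source,
                                "df": df, "H": h, "p": p,
                                "signif": significance_stars(p, alpha)})
                if source == "entry" and p < alpha:
                    pairs = dunn_bonferroni(groups, labels)
                    pairs.insert(0, "trait", trait)
                    pairs.insert(0, "set", set_id)
                    dunn_frames.append(pairs)
                    sig = {(r.group_i, r.group_j): bool(r.p_adj < alpha)
                           for r in pairs.itertuples()}
                    letters = compact_letters(sig, labels)
                    for entry, letter in letters.items():
                        letter_rows.append({"set": set_id, "trait": trait,
                                            "entry": entry, "letters": letter})

    report: dict[str, pd.DataFrame] = {
        "shapiro": pd.DataFrame(shapiro_rows),
        "kw_tests": pd.DataFrame(kw_rows),
        "dunn_pairs": (pd.concat(dunn_frames, ignore_index=True)
                       if dunn_frames else pd.DataFrame()),
        "letters": pd.DataFrame(letter_rows),
    }
    for set_id in sets:
        corr = spearman_matrix(trait_table, traits_present, set_id=set_id)
        report[f"spearman_set{set_id}"] = corr.rho
        report[f"spearman_set{set_id}_p"] = corr.p

    variable_sets = {"gt_rgbvi": [t for t in ALL_TRAITS if t in traits_present],
                     "gt": [t for t in GROWTH_TRAITS if t in traits_present],
                     "rgbvi": [t for t in VI_TRAITS if t in traits_present]}
    load_frames, var_rows = [], []
    for name, cols in variable_sets.items():
        if len(cols) < 2:
            continue
        pca = pca_traits(trait_table, cols, abs_exr=True)
        loadings = pca.loadings.iloc[:, :2].copy()
        loadings.insert(0, "variable", loadings.index)
        loadings.insert(0, "variable_set", name)
        load_frames.append(loadings.reset_index(drop=True))
        for j, pct in enumerate(pca.explained_pct):
            var_rows.append({"variable_set": name, "component": f"PC{j + 1}",
                             "explained_pct": pct})
    report["pca_loadings"] = (pd.concat(load_frames, ignore_index=True)
                              if load_frames else pd.DataFrame())
    report["pca_variance"] = pd.DataFrame(var_rows)
    return report
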