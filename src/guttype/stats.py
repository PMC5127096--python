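"""Hypothesis tests, multiple-comparison handling, compact letter displays,
Kendall tau-b correlation networks, and the lean/obese BMI stratification.

Conventions: group means of numerical data (relative abundances) are compared
with Welch's t test, ordinal questionnaire scores with the Mann-Whitney U
test, and prevalences with Fisher's exact test; families of pairwise tests
are Holm-corrected.  Correlation networks keep taxon/item pairs with
P < 0.001 and |tau| > 0.2 (both thresholds configurable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceTable

__all__ = [
    "TestResult",
    "CorrelationEdge",
    "CorrelationNetwork",
    "ConstantInputError",
    "StratificationError",
    "welch_t",
    "mann_whitney_u",
    "fisher_exact",
    "holm_adjust",
    "compact_letters",
    "kendall_tau_b",
    "build_network",
    "bmi_strata_compare",
    "group_abundance_report",
    "significance_stars",
]


class ConstantInputError(ValueError):
    """Correlation undefined because one variable is constant."""


class StratificationError(ValueError):
    """A required stratum (e.g. lean or obese) is empty."""


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    group_sizes: tuple[int, ...]
    effect_direction: int  # sign of (first group - second group), 0 if none


def significance_stars(p: float, levels: tuple[float, float] = (0.05, 0.01)) -> str:
    """'**' below the stricter level, '*' below the looser one, else 'NS'."""
    if p < levels[1]:
        return "**"
    if p < levels[0]:
        return "*"
    return "NS"


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite df, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch's t test needs at least two observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        same = np.isclose(x.mean(), y.mean())
        stat, p = (0.0, 1.0) if same else (np.inf * np.sign(x.mean() - y.mean()), 0.0)
    else:
        stat, p = sps.ttest_ind(x, y, equal_var=False)
    diff = x.mean() - y.mean()
    return TestResult(float(stat), float(p), "welch_t", (x.size, y.size), int(np.sign(diff)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test, two-sided.

    Exact enumeration when both groups have n <= 8 and no ties; otherwise the
    tie-corrected normal approximation with continuity correction.  When every
    value is identical the test carries no information and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("Mann-Whitney U needs at least one observation per group")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        u = x.size * y.size / 2.0
        return TestResult(float(u), 1.0, "mann_whitney_u", (x.size, y.size), 0)
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    direction = int(np.sign(res.statistic - x.size * y.size / 2.0))
    return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney_u",
                      (x.size, y.size), direction)


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test on a 2x2 table; two-sided probability-mass rule."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    if (arr < 0).any():
        raise ValueError("table cells must be nonnegative")
    if arr.sum() < 1:
        raise ValueError("table must contain at least one observation")
    stat, p = sps.fisher_exact(arr, alternative="two-sided")
    # direction of the association: sign of a*d - b*c
    direction = int(np.sign(arr[0, 0] * arr[1, 1] - arr[0, 1] * arr[1, 0]))
    sizes = (int(arr[0].sum()), int(arr[1].sum()))
    return TestResult(float(stat), float(p), "fisher_exact", sizes, direction)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def compact_letters(
    groups: Sequence[str],
    pairwise_adjusted_p: pd.DataFrame | np.ndarray | Mapping[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display: two groups share a letter iff adjusted p >= alpha.

    Letters correspond to cliques of the "not significantly different" graph
    covering all of its edges; for up to 12 groups an exhaustive search over
    maximal cliques yields a minimal letter count, larger problems fall back
    to a greedy cover.
    """
    groups = list(groups)
    pmat = _as_p_matrix(groups, pairwise_adjusted_p)
    if not np.allclose(pmat, pmat.T, equal_nan=True):
        raise ValueError("pairwise p-value matrix must be symmetric")
    n = len(groups)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if pmat[i, j] >= alpha:
            g.add_edge(i, j)
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    edges = {frozenset(e) for e in g.edges}
    cover = _min_clique_cover(cliques, edges, set(range(n))) if n <= 12 else None
    if cover is None:
        cover = _greedy_clique_cover(cliques, edges, set(range(n)))
    # stable letter order: by smallest member index
    cover = sorted(cover, key=lambda c: (min(c), sorted(c)))
    letters = {group: "" for group in groups}
    for letter, clique in zip(_letter_stream(), cover):
        for idx in sorted(clique):
            letters[groups[idx]] += letter
    return letters


def _as_p_matrix(groups, p) -> np.ndarray:
    n = len(groups)
    if isinstance(p, pd.DataFrame):
        return p.loc[groups, groups].to_numpy(dtype=float)
    if isinstance(p, Mapping):
        mat = np.ones((n, n))
        index = {g: i for i, g in enumerate(groups)}
        for (a, b), val in p.items():
            mat[index[a], index[b]] = val
            mat[index[b], index[a]] = val
        return mat
    return np.asarray(p, dtype=float)


def _min_clique_cover(cliques, edges, vertices):
    for r in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, r):
            covered_e = set()
            covered_v = set()
            for c in combo:
                covered_v |= c
                covered_e |= {frozenset(p) for p in itertools.combinations(sorted(c), 2)}
            if edges <= covered_e and vertices <= covered_v:
                return list(combo)
    return None


def _greedy_clique_cover(cliques, edges, vertices):
    remaining_e = set(edges)
    remaining_v = set(vertices)
    cover = []
    while remaining_e or remaining_v:
        best = max(
            cliques,
            key=lambda c: (
                len(remaining_e & {frozenset(p) for p in itertools.combinations(sorted(c), 2)})
                + len(remaining_v & c)
            ),
        )
        cover.append(best)
        remaining_e -= {frozenset(p) for p in itertools.combinations(sorted(best), 2)}
        remaining_v -= best
    return cover


def _letter_stream():
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)


@dataclass
class CorrelationEdge:
    a: str
    b: str
    tau: float
    p_value: float


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> CorrelationEdge:
    """Kendall tau-b with tie correction; p from the tie-adjusted normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("Kendall tau-b needs at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ConstantInputError("tau-b undefined when a variable is constant")
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationEdge("x", "y", float(res.statistic), float(res.pvalue))


@dataclass
class CorrelationNetwork:
    """Filtered tau-b edges between taxa and/or questionnaire items."""

    nodes: list[str]
    edges: list[CorrelationEdge]
    p_threshold: float = 0.001
    tau_threshold: float = 0.2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.a, e.b, e.tau, e.p_value) for e in self.edges],
            columns=["a", "b", "tau", "p"],
        )

    def write_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# filters: p < {self.p_threshold}, |tau| > {self.tau_threshold}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.a, e.b, tau=e.tau, p=e.p_value)
        return g


def build_network(
    table: AbundanceTable,
    items: pd.DataFrame | None = None,
    p_threshold: float = 0.001,
    tau_threshold: float = 0.2,
    taxon_pairs: bool = True,
) -> CorrelationNetwork:
    """Kendall tau-b network over taxon-taxon (and item-taxon) pairs.

    Edges are retained iff p < *p_threshold* and |tau| > *tau_threshold*.
    Pairs involving a constant variable are undefined and silently excluded.
    """
    if table.kind != "relative":
        raise ValueError("build_network expects a relative-abundance table")
    taxa = table.taxon_ids
    nodes = list(taxa)
    pairs: list[tuple[str, np.ndarray, str, np.ndarray]] = []
    data = table.data
    if taxon_pairs:
        for a, b in itertools.combinations(taxa, 2):
            pairs.append((a, data[a].to_numpy(), b, data[b].to_numpy()))
    if items is not None:
        items = items.loc[table.sample_ids]
        nodes += list(items.columns)
        for item in items.columns:
            scores = items[item].to_numpy(dtype=float)
            for taxon in taxa:
                pairs.append((item, scores, taxon, data[taxon].to_numpy()))
    edges = []
    for a, xa, b, xb in pairs:
        mask = ~(np.isnan(xa) | np.isnan(xb))
        if mask.sum() < 3:
            continue
        try:
            edge = kendall_tau_b(xa[mask], xb[mask])
        except ConstantInputError:
            continue
        if edge.p_value < p_threshold and abs(edge.tau) > tau_threshold:
            edges.append(CorrelationEdge(a, b, edge.tau, edge.p_value))
    return CorrelationNetwork(nodes, edges, p_threshold, tau_threshold)


def bmi_strata_compare(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    item: str = "Q7",
    taxa: Sequence[str] | None = None,
    lean_below: float = 25.0,
    obese_above: float = 30.0,
) -> pd.DataFrame:
    """Lean (BMI < 25) vs obese (BMI > 30) comparison; the middle is excluded.

    Each taxon's relative abundance (as percent) is compared with Welch's t,
    its prevalence with Fisher's exact test; the ordinal *item* score with the
    Mann-Whitney U test.  Significance stars at 0.05 (*) and 0.01 (**).
    """
    if table.kind != "relative":
        raise ValueError("bmi_strata_compare expects a relative-abundance table")
    if "bmi" not in metadata.columns:
        raise ValueError("metadata must contain a 'bmi' column")
    meta = metadata.loc[metadata.index.intersection(table.sample_ids)]
    bmi = meta["bmi"].astype(float)
    lean_ids = meta.index[bmi < lean_below].tolist()
    obese_ids = meta.index[bmi > obese_above].tolist()
    if not lean_ids or not obese_ids:
        raise StratificationError(
            f"empty stratum: lean n={len(lean_ids)}, obese n={len(obese_ids)}"
        )
    taxa = list(taxa) if taxa is not None else table.taxon_ids
    lean = table.subset(lean_ids)
    obese = table.subset(obese_ids)
    rows = []
    if item is not None and item in metadata.columns:
        xs = metadata.loc[lean_ids, item].dropna().to_numpy(dtype=float)
        ys = metadata.loc[obese_ids, item].dropna().to_numpy(dtype=float)
        res = mann_whitney_u(xs, ys)
        rows.append(
            {
                "variable": item,
                "lean_mean": xs.mean(),
                "lean_sd": xs.std(ddof=1),
                "obese_mean": ys.mean(),
                "obese_sd": ys.std(ddof=1),
                "p_abundance": res.p_value,
                "sig_abundance": significance_stars(res.p_value),
                "lean_prevalence": np.nan,
                "obese_prevalence": np.nan,
                "p_prevalence": np.nan,
                "sig_prevalence": "",
                "test": "mann_whitney_u",
            }
        )
    for taxon in taxa:
        xl = 100.0 * lean.data[taxon].to_numpy()
        xo = 100.0 * obese.data[taxon].to_numpy()
        res = welch_t(xl, xo)
        lp, op = int((xl > 0).sum()), int((xo > 0).sum())
        fisher = fisher_exact([[lp, len(xl) - lp], [op, len(xo) - op]])
        rows.append(
            {
                "variable": taxon,
                "lean_mean": xl.mean(),
                "lean_sd": xl.std(ddof=1),
                "obese_mean": xo.mean(),
                "obese_sd": xo.std(ddof=1),
                "p_abundance": res.p_value,
                "sig_abundance": significance_stars(res.p_value),
                "lean_prevalence": 100.0 * lp / len(xl),
                "obese_prevalence": 100.0 * op / len(xo),
                "p_prevalence": fisher.p_value,
                "sig_prevalence": significance_stars(fisher.p_value),
                "test": "welch_t/fisher_exact",
            }
        )
    out = pd.DataFrame(rows).set_index("variable")
    out.attrs["n_lean"] = len(lean_ids)
    out.attrs["n_obese"] = len(obese_ids)
    return out


def group_abundance_report(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    by: str,
    taxa: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon group means (percent +/- SD) with Holm-corrected pairwise
    Welch tests summarized as compact letters."""
    if table.kind != "relative":
        raise ValueError("group_abundance_report expects a relative-abundance table")
    if by not in metadata.columns:
        raise ValueError(f"metadata has no column {by!r}")
    meta = metadata.loc[metadata.index.intersection(table.sample_ids)]
    meta = meta[meta[by].notna()]
    groups = list(pd.unique(meta[by]))
    members = {g: meta.index[meta[by] == g].tolist() for g in groups}
    taxa = list(taxa) if taxa is not None else table.taxon_ids
    rows = []
    for taxon in taxa:
        pct = 100.0 * table.data[taxon]
        pair_list = list(itertools.combinations(groups, 2))
        raw = [welch_t(pct.loc[members[a]], pct.loc[members[b]]).p_value for a, b in pair_list]
        adj = holm_adjust(raw) if raw else np.array([])
        pmap = {pair: p for pair, p in zip(pair_list, adj)}
        letters = compact_letters(groups, pmap, alpha=alpha)
        any_sig = bool((adj < alpha).any()) if raw else False
        row: dict[str, object] = {"taxon": taxon}
        for g in groups:
            vals = pct.loc[members[g]]
            suffix = letters[g] if any_sig else ""
            row[g] = f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}" + (
                f" ^{suffix}^" if suffix else ""
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon")
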