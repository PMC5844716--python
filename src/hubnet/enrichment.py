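"""Over-representation analysis of differential gene lists.

For each annotated term the 2x2 table is

    n_f  = differential genes inside the term
    n    = genes in the term
    N_f  = differential genes in the tested universe
    N    = genes in the tested universe

and the enrichment ratio is Re = (n_f/n) / (N_f/N): the fraction of the term
that is differential relative to the array-wide differential fraction.
Significance comes from the one-sided Fisher exact (hypergeometric tail)
test; a Pearson chi-square statistic is reported alongside but is flagged
invalid (and never used for selection) when any expected cell is below 5.

Up- and down-regulated gene lists are analyzed separately (plus a combined
"both" pass used for coloring term networks), and Benjamini-Hochberg FDR is
applied within each category x direction family. The tested universe in a
category is the set of genes carrying at least one annotation there —
unannotated genes cannot enter any table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from hubnet import io
from hubnet.diffexpr import bh_fdr

logger = logging.getLogger(__name__)

CATEGORIES = ("GO", "KEGG", "BioCarta", "Reactome")
PATHWAY_CATEGORIES = ("KEGG", "BioCarta", "Reactome")

ENRICHMENT_COLUMNS = [
    "term_id",
    "name",
    "category",
    "direction",
    "n_f",
    "n",
    "N_f",
    "N",
    "Re",
    "p_value",
    "fdr",
    "chi2_p",
    "chi2_valid",
    "significant",
]


@dataclass
class GeneSetCollection:
    """Annotated gene sets: (term_id, name, category, members) plus universe."""

    terms: list[tuple[str, str, str, list[str]]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = set()
        for term_id, _, category, members in self.terms:
            if term_id in seen:
                raise ValueError(f"duplicate term id {term_id!r}")
            seen.add(term_id)
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r} for {term_id!r}")
            if not members:
                raise ValueError(f"term {term_id!r} has no members")
        if not self.universe:
            self.universe = {g for *_, members in self.terms for g in members}
        for term_id, _, _, members in self.terms:
            extra = set(members) - self.universe
            if extra:
                raise ValueError(f"term {term_id!r} has members outside the universe: {sorted(extra)[:5]}")

    def of_category(self, category: str) -> list[tuple[str, str, str, list[str]]]:
        return [t for t in self.terms if t[2] == category]

    def category_universe(self, category: str) -> set[str]:
        return {g for *_, cat, members in [(t[0], t[1], t[2], t[3]) for t in self.terms] if cat == category for g in members}

    def members_of(self, term_id: str) -> set[str]:
        for tid, _, _, members in self.terms:
            if tid == term_id:
                return set(members)
        raise KeyError(term_id)

    def membership(self) -> dict[str, set[str]]:
        """gene -> set of term ids."""
        out: dict[str, set[str]] = {}
        for term_id, _, _, members in self.terms:
            for g in members:
                out.setdefault(g, set()).add(term_id)
        return out

    # GMT uses two leading columns; the category is carried in the
    # description field as "category|name" so the file stays standard.
    def to_gmt(self, path: str | Path) -> None:
        io.write_gmt(
            [(tid, f"{cat}|{name}", members) for tid, name, cat, members in self.terms],
            path,
        )

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        terms = []
        for term_id, description, members in io.read_gmt(path):
            if "|" in description:
                category, name = description.split("|", 1)
            else:
                category, name = "GO", description
            terms.append((term_id, name, category, members))
        return cls(terms)


# ---------------------------------------------------------------------------
# elementary statistics


def _check_margins(n_f: int, n: int, N_f: int, N: int) -> None:
    if min(n_f, n, N_f, N) < 0 or n > N or N_f > N or n_f > min(n, N_f):
        raise ValueError(f"inconsistent 2x2 margins: n_f={n_f}, n={n}, N_f={N_f}, N={N}")


def enrichment_ratio(n_f: int, n: int, N_f: int, N: int) -> float:
    """Re = (n_f/n) / (N_f/N)."""
    if n <= 0 or N_f <= 0 or N <= 0:
        raise ValueError("n, N_f and N must be positive")
    _check_margins(n_f, n, N_f, N)
    return (n_f / n) / (N_f / N)


def fisher_term_test(n_f: int, n: int, N_f: int, N: int) -> float:
    """One-sided over-representation p: P(X >= n_f), X ~ Hypergeom(N, n, N_f)."""
    _check_margins(n_f, n, N_f, N)
    return float(stats.hypergeom(N, n, N_f).sf(n_f - 1))


def chi2_term_test(n_f: int, n: int, N_f: int, N: int) -> tuple[float, float, bool]:
    """Pearson chi-square on the 2x2 table, 1 df, no continuity correction.

    Returns ``(statistic, p, valid)``; ``valid`` is False when any expected
    cell is below 5, in which case selection must fall back to Fisher.
    """
    _check_margins(n_f, n, N_f, N)
    table = [[n_f, n - n_f], [N_f - n_f, N - n - N_f + n_f]]
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        # a zero margin: no association testable
        return 0.0, 1.0, False
    result = stats.chi2_contingency(table, correction=False)
    valid = bool((expected >= 5).all())
    return float(result.statistic), float(result.pvalue), valid


# ---------------------------------------------------------------------------
# term screening


def _enrich_one_direction(
    terms, universe: set[str], de: set[str], direction: str, category: str
) -> list[dict]:
    N = len(universe)
    N_f = len(de)
    rows = []
    for term_id, name, _, members in terms:
        members = set(members) & universe
        n = len(members)
        n_f = len(members & de)
        if N_f > 0:
            p = fisher_term_test(n_f, n, N_f, N)
            re = enrichment_ratio(n_f, n, N_f, N)
            chi_stat, chi_p, chi_valid = chi2_term_test(n_f, n, N_f, N)
        else:
            p, re, chi_p, chi_valid = 1.0, float("nan"), 1.0, False
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "category": category,
                "direction": direction,
                "n_f": n_f,
                "n": n,
                "N_f": N_f,
                "N": N,
                "Re": re,
                "p_value": p,
                "chi2_p": chi_p,
                "chi2_valid": chi_valid,
            }
        )
    return rows


def enrich(
    collection: GeneSetCollection,
    up_genes,
    down_genes,
    p_cut: float = 0.05,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Screen every term for over-representation of the differential lists.

    One record per term per direction (``up``, ``down`` and the combined
    ``both`` list); FDR within category x direction; ``significant`` is
    strict p < p_cut and FDR < fdr_cut on the Fisher p.
    """
    up = set(up_genes)
    down = set(down_genes)
    if not collection.universe:
        raise ValueError("empty annotation universe")
    outside = (up | down) - collection.universe
    if outside:
        logger.info("dropping %d differential genes without any annotation", len(outside))
    frames = []
    for category in CATEGORIES:
        terms = collection.of_category(category)
        if not terms:
            continue
        universe = {g for *_, members in terms for g in members}
        for direction, de in (("up", up), ("down", down), ("both", up | down)):
            rows = _enrich_one_direction(terms, universe, de & universe, direction, category)
            df = pd.DataFrame(rows)
            df["fdr"] = bh_fdr(df["p_value"].to_numpy())
            frames.append(df)
    if not frames:
        raise ValueError("collection contains no terms")
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = (out["p_value"] < p_cut) & (out["fdr"] < fdr_cut)
    return out[ENRICHMENT_COLUMNS]


def significant_terms(records: pd.DataFrame, category: str | None = None) -> pd.DataFrame:
    sel = records.loc[records["significant"].astype(bool)]
    if category is not None:
        if category == "pathway":
            sel = sel[sel["category"].isin(PATHWAY_CATEGORIES)]
        else:
            sel = sel[sel["category"] == category]
    return sel.reset_index(drop=True)


def term_regulation(records: pd.DataFrame) -> dict[str, str]:
    """Term id -> up/down/both from per-direction significance.

    A term significant in the ``up`` pass only is colored "up", in the
    ``down`` pass only "down"; significant in both (or only in the combined
    pass) is "both".
    """
    sig = records.loc[records["significant"].astype(bool)]
    up = set(sig.loc[sig["direction"] == "up", "term_id"])
    down = set(sig.loc[sig["direction"] == "down", "term_id"])
    both = set(sig.loc[sig["direction"] == "both", "term_id"])
    out = {}
    for term in up | down | both:
        if term in up and term in down:
            out[term] = "both"
        elif term in up:
            out[term] = "up"
        elif term in down:
            out[term] = "down"
        else:
            out[term] = "both"
    return out


def write_enrichment_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_enrichment_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
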