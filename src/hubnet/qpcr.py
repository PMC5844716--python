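"""Relative quantification by the Livak 2^-ddCt method and trend concordance.

Per sample, dCt = Ct(gene) - Ct(reference); ddCt is the difference of the
group-mean dCt values (experimental minus control) and the relative
expression ratio is 2^-ddCt. Averaging replicate dCt arithmetically equals
taking the geometric mean of per-replicate 2^-dCt values, the natural scale
for exponential amplification. The ratio is invariant to any constant added
to every Ct (reference normalization) and label swapping maps it to its
reciprocal.

Concordance against the microarray screen is trend agreement: a validation
ratio and a microarray fold change agree when they fall on the same side of
1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from hubnet.diffexpr import CONTROL, EXPERIMENTAL

DEFAULT_REFERENCE = "Actb"

CT_MIN, CT_MAX = 0.0, 45.0


@dataclass
class CtTable:
    """qPCR threshold cycles: rows (gene, sample, group, ct) + reference gene."""

    data: pd.DataFrame
    reference_gene: str = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        required = {"gene", "sample", "group", "ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        ct = self.data["ct"]
        if ((ct <= CT_MIN) | (ct >= CT_MAX)).any():
            raise ValueError(f"Ct values must lie in ({CT_MIN}, {CT_MAX})")
        samples = set(self.data["sample"])
        ref_samples = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        missing = samples - ref_samples
        if missing:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing in samples: {sorted(missing)}"
            )

    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - {self.reference_gene})


def ddct_ratio(table: CtTable, gene: str) -> float:
    """Relative expression 2^-ddCt of ``gene`` vs the reference gene."""
    df = table.data
    ref = df[df["gene"] == table.reference_gene].set_index("sample")["ct"]
    tgt = df[df["gene"] == gene]
    if tgt.empty:
        raise ValueError(f"gene {gene!r} not present in the Ct table")
    for grp in (EXPERIMENTAL, CONTROL):
        if not (tgt["group"] == grp).any():
            raise ValueError(f"gene {gene!r} has no measurements in group {grp!r}")
    dct = tgt["ct"].to_numpy() - ref.loc[tgt["sample"]].to_numpy()
    per_group = pd.Series(dct, index=tgt["group"].values).groupby(level=0).mean()
    ddct = per_group[EXPERIMENTAL] - per_group[CONTROL]
    return float(2.0 ** (-ddct))


def all_ratios(table: CtTable) -> pd.DataFrame:
    rows = [{"gene": g, "ratio": ddct_ratio(table, g)} for g in table.genes()]
    return pd.DataFrame(rows, columns=["gene", "ratio"])


def concordance(
    microarray_records: pd.DataFrame, qpcr_ratios: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Trend agreement between screening fold changes and qPCR ratios.

    Returns the per-gene table and the agreeing fraction over the genes
    present in both inputs.
    """
    fc = microarray_records.set_index("gene")["fold_change"]
    rows = []
    for row in qpcr_ratios.itertuples(index=False):
        if row.gene not in fc.index:
            continue
        array_fc = float(fc.loc[row.gene])
        agree = (array_fc > 1.0) == (row.ratio > 1.0) and array_fc != 1.0 and row.ratio != 1.0
        rows.append(
            {
                "gene": row.gene,
                "microarray_fold_change": array_fc,
                "qpcr_ratio": float(row.ratio),
                "agree": bool(agree),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "microarray_fold_change", "qpcr_ratio", "agree"])
    fraction = float(out["agree"].mean()) if len(out) else float("nan")
    return out, fraction


def write_ratio_tsv(ratios: pd.DataFrame, path: str | Path) -> None:
    ratios.to_csv(path, sep="\t", index=False)
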