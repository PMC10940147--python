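"""Quantify editing outcomes from per-position base-count tables.

Input is a pileup-derived table (position, ref, nA, nC, nG, nT) for a
treated and a control amplicon. Per position the module computes the
conversion frequency, a two-sided Fisher's exact p-value against the
control, a SNP flag when the control also carries the variant, and the
attributed strand: for an A-to-G editor a converted ref-A is a top-strand
edit and a converted ref-T a bottom-strand edit (the actual edited A sits
on the bottom strand); for a C-to-T editor, ref-C is top and ref-G bottom.

A call is significant when p < alpha, the treated frequency exceeds the
sequencing-error noise floor (0.10% by default) and the SNP flag is unset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact

from .genome import complement

BASES = ("A", "C", "G", "T")

#: ref base -> (product base, attributed strand), per editor class
CONVERSIONS = {
    "ABE": {"A": ("G", "top"), "T": ("C", "bottom")},
    "CBE": {"C": ("T", "top"), "G": ("A", "bottom")},
}


@dataclass
class CountTable:
    """Per-position base counts for one amplicon sample."""

    data: pd.DataFrame  # columns: position, ref, A, C, G, T
    sample: str = ""

    def __post_init__(self) -> None:
        required = {"position", "ref", *BASES}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"count table missing columns {sorted(missing)}")
        if (self.data[list(BASES)] < 0).any().any():
            raise ValueError("negative counts")
        self.data = self.data.reset_index(drop=True)

    @property
    def depth(self) -> pd.Series:
        return self.data[list(BASES)].sum(axis=1)

    @classmethod
    def read_tsv(cls, path: str | Path, sample: str | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        rename = {c: c[1:] for c in df.columns if c in ("nA", "nC", "nG", "nT")}
        df = df.rename(columns=rename)
        return cls(df, sample=sample or Path(path).stem)

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.rename(columns={b: f"n{b}" for b in BASES})
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EditCall:
    position: int
    conversion: str  # e.g. "A>G"
    treated_freq: float
    control_freq: float
    p_value: float
    significant: bool
    snp_flag: bool
    attributed_strand: str


def editing_efficiency(row: pd.Series, product: str) -> float:
    """Product-base count over depth for one table row."""
    depth = sum(int(row[b]) for b in BASES)
    if depth == 0:
        raise ValueError(f"zero depth at position {row['position']}")
    return int(row[product]) / depth


def fisher_edit_test(treated: tuple[int, int], control: tuple[int, int]) -> float:
    """Two-sided exact p-value of the 2x2 table
    [[treated edited, treated unedited], [control edited, control unedited]]."""
    (a, b), (c, d) = treated, control
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def product_purity(row: pd.Series, ref: str, intended_product: str) -> float | None:
    """Intended-product reads over all non-reference reads; None when no
    non-reference base was observed."""
    nonref = sum(int(row[b]) for b in BASES if b != ref)
    if nonref == 0:
        return None
    return int(row[intended_product]) / nonref


def call_edits(treated: CountTable, control: CountTable, editor: str = "ABE",
               alpha: float = 0.05, floor: float = 0.001,
               bh_correct: bool = False) -> list[EditCall]:
    """Per-position edit calls for the editor's two conversions.

    ``floor`` is the sequencing-error level: treated frequencies must exceed
    it to be called, and a control frequency above it marks the position as
    a pre-existing SNP. Raw p-values are used by default; ``bh_correct``
    applies Benjamini-Hochberg across the window.
    """
    if editor not in CONVERSIONS:
        raise ValueError("editor must be 'ABE' or 'CBE'")
    t, c = treated.data, control.data
    if not t["position"].equals(c["position"]) or not t["ref"].equals(c["ref"]):
        raise ValueError("treated and control tables cover different positions")
    conv = CONVERSIONS[editor]
    calls: list[EditCall] = []
    for i in range(len(t)):
        ref = t.at[i, "ref"]
        if ref not in conv:
            continue
        product, strand = conv[ref]
        t_depth = sum(int(t.at[i, b]) for b in BASES)
        c_depth = sum(int(c.at[i, b]) for b in BASES)
        if t_depth == 0 or c_depth == 0:
            raise ValueError(f"zero depth at position {t.at[i, 'position']}")
        t_ed, c_ed = int(t.at[i, product]), int(c.at[i, product])
        t_freq, c_freq = t_ed / t_depth, c_ed / c_depth
        p = fisher_edit_test((t_ed, t_depth - t_ed), (c_ed, c_depth - c_ed))
        snp = c_freq > floor
        calls.append(EditCall(
            position=int(t.at[i, "position"]), conversion=f"{ref}>{product}",
            treated_freq=t_freq, control_freq=c_freq, p_value=p,
            significant=False, snp_flag=snp, attributed_strand=strand))
    pvals = [c.p_value for c in calls]
    if bh_correct and calls:
        from statsmodels.stats.multitest import multipletests
        pvals = list(multipletests([c.p_value for c in calls], method="fdr_bh")[1])
    out = []
    for call, p_adj in zip(calls, pvals):
        sig = (p_adj < alpha) and (call.treated_freq > floor) and not call.snp_flag
        out.append(EditCall(call.position, call.conversion, call.treated_freq,
                            call.control_freq, call.p_value, sig, call.snp_flag,
                            call.attributed_strand))
    return out


def strand_profile(calls: list[EditCall], significant_only: bool = False,
                   ) -> dict[str, float]:
    """Summed treated frequencies per attributed strand and the bias index
    top/(top+bottom) — 1.0 for pure top-strand editing, 0.5 when balanced."""
    use = [c for c in calls if c.significant] if significant_only else calls
    if not use:
        raise ValueError("no calls to profile")
    top = sum(c.treated_freq for c in use if c.attributed_strand == "top")
    bottom = sum(c.treated_freq for c in use if c.attributed_strand == "bottom")
    if top + bottom == 0:
        return {"top_sum": 0.0, "bottom_sum": 0.0, "bias_index": float("nan")}
    return {"top_sum": top, "bottom_sum": bottom,
            "bias_index": top / (top + bottom)}


def calls_to_table(calls: list[EditCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "position": c.position, "conversion": c.conversion,
        "treated_freq": c.treated_freq, "control_freq": c.control_freq,
        "p_value": c.p_value, "significant": c.significant,
        "snp_flag": c.snp_flag, "strand": c.attributed_strand,
    } for c in calls])
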