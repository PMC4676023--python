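"""qPCR-level quantification: ChIP percent-input, ddCt fold change,
knockdown/control occupancy ratios, methylation-resistance fractions, and
the two-sample t-test used for all pairwise comparisons.

All computations assume perfect amplification efficiency (one Ct cycle =
one two-fold change in template), the convention of the ddCt method.
Replicates are biological (independent experiments); technical wells
should be averaged before they enter these tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

QPCR_COLUMNS = ["sample_id", "condition", "assay", "target", "ct", "input_fraction"]


def load_qpcr_table(path) -> pd.DataFrame:
    """Read a tidy Ct table (CSV or TSV) and validate its schema."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(QPCR_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if "input_fraction" not in df.columns:
        df["input_fraction"] = np.nan
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return df


def load_primer_table() -> pd.DataFrame:
    """The rDNA/reference primer panel (name, forward, reverse 5'->3')."""
    with resources.files("rdnachip.data").joinpath("primers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def percent_input(ct_ip, ct_input, input_fraction: float = 0.1):
    """ChIP recovery as a percentage of the dilution-adjusted input.

    The input Ct is first adjusted for the fraction of chromatin it
    represents (adjusted = ct_input - log2(1 / input_fraction)); the
    percentage is 100 * 2^(adjusted - ct_ip). Accepts scalars or arrays.
    """
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must lie in (0, 1]")
    if (ct_ip <= 0).any() or (ct_input <= 0).any():
        raise ValueError("Ct values must be > 0")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    out = 100.0 * np.power(2.0, adjusted - ct_ip)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FoldChangeEstimate:
    point: float
    dispersion: float
    n: int

    def __post_init__(self):
        if self.point <= 0:
            raise ValueError("fold change must be > 0")
        if self.n < 2:
            raise ValueError("need >= 2 replicates")


def ddct_fold_change(
    table: pd.DataFrame,
    target: str,
    reference_gene: str = "GAPDH",
    assay: str = "rt",
    control: str = "control",
    treatment: str = "treatment",
) -> FoldChangeEstimate:
    """Relative quantification by the ddCt method.

    ddCt = (mean Ct_target - mean Ct_ref) in treatment minus the same
    difference in control; fold = 2^-ddCt. The dispersion is the sd of
    per-replicate treatment folds (each treatment replicate's dCt against
    the mean control dCt).
    """
    sub = table[table["assay"] == assay]

    def cts(tgt: str, cond: str) -> np.ndarray:
        v = sub[(sub["target"] == tgt) & (sub["condition"] == cond)]["ct"].to_numpy()
        if v.size == 0:
            raise ValueError(f"no Ct rows for target {tgt!r} in condition {cond!r}")
        return v

    t_trt, t_ctl = cts(target, treatment), cts(target, control)
    r_trt, r_ctl = cts(reference_gene, treatment), cts(reference_gene, control)
    dct_ctl = float(np.mean(t_ctl) - np.mean(r_ctl))
    ddct = (float(np.mean(t_trt)) - float(np.mean(r_trt))) - dct_ctl
    point = 2.0 ** (-ddct)
    n = min(t_trt.size, r_trt.size)
    rep_dct = t_trt[:n] - r_trt[:n]
    rep_folds = 2.0 ** (-(rep_dct - dct_ctl))
    dispersion = float(np.std(rep_folds, ddof=1)) if n >= 2 else 0.0
    return FoldChangeEstimate(point=point, dispersion=dispersion, n=int(n))


def occupancy_ratio(percent_kd: float, percent_ctrl: float) -> float:
    """Ratio of ChIP occupancy (percent input) in knockdown vs control."""
    if percent_ctrl <= 0:
        raise ValueError("control percent input must be > 0")
    return percent_kd / percent_ctrl


def occupancy_ratios(
    percents_kd: Sequence[float], percents_ctrl: Sequence[float]
) -> FoldChangeEstimate:
    """Replicate-wise occupancy ratios aggregated as mean +/- sd."""
    kd = np.asarray(percents_kd, dtype=float)
    ctrl = np.asarray(percents_ctrl, dtype=float)
    if kd.shape != ctrl.shape:
        raise ValueError("replicate arrays must have equal length")
    if (ctrl <= 0).any():
        raise ValueError("control percent input must be > 0")
    ratios = kd / ctrl
    return FoldChangeEstimate(
        point=float(np.mean(ratios)),
        dispersion=float(np.std(ratios, ddof=1)),
        n=int(ratios.size),
    )


@dataclass(frozen=True)
class MethylationFraction:
    """Fraction of template resistant to a methylation-sensitive digest.

    ``censored`` marks no-amplification samples (Ct at the cycle ceiling),
    reported as "< floor"; ``clipped`` marks fractions above 1, which are
    physically impossible and signal assay noise.
    """

    value: float
    censored: bool = False
    clipped: bool = False

    def __str__(self) -> str:
        if self.censored:
            return f"< {self.value:.3g}"
        return f"{self.value:.3g}"


def methylation_fraction(
    ct_digested: float | None,
    ct_undigested: float,
    max_cycles: float = 40.0,
) -> MethylationFraction:
    """Resistant (methylated) fraction from a HpaII-type digestion qPCR.

    fraction = 2^(ct_undigested - ct_digested): template cut by the
    enzyme fails to amplify, so only the resistant fraction contributes.
    A missing or at-ceiling digested Ct is censored at the detection
    floor (the fraction that would give Ct = max_cycles). An MspI digest
    (methylation-insensitive) of the same site should always censor.
    """
    if ct_undigested <= 0:
        raise ValueError("Ct values must be > 0")
    if ct_digested is None or ct_digested >= max_cycles:
        return MethylationFraction(2.0 ** (ct_undigested - max_cycles), censored=True)
    if ct_digested <= 0:
        raise ValueError("Ct values must be > 0")
    frac = 2.0 ** (ct_undigested - ct_digested)
    if frac > 1.0:
        return MethylationFraction(1.0, clipped=True)
    return MethylationFraction(frac)


class TTestResult(NamedTuple):
    t: float
    p: float
    df: float
    degenerate: bool = False


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> TTestResult:
    """Two-sided two-sample t-test (Welch by default).

    Degenerate inputs (zero variance in both groups) return t=0, p=1 when
    the means agree, and p=0 with the ``degenerate`` flag set when they do
    not — the difference is then certain but no finite t exists.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    df_pooled = a.size + b.size - 2
    if np.var(a) == 0 and np.var(b) == 0:
        if math.isclose(float(np.mean(a)), float(np.mean(b))):
            return TTestResult(0.0, 1.0, float(df_pooled))
        return TTestResult(math.inf, 0.0, float(df_pooled), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    if t == 0.0:
        p = 1.0
    return TTestResult(t, p, float(res.df))


def significance_stars(p: float) -> str:
    """The figure-legend convention: '**' for p < 0.01, '*' for
    0.01 < p < 0.05, otherwise no label (boundaries are unlabeled)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.01:
        return "**"
    if 0.01 < p < 0.05:
        return "*"
    return ""


def percent_input_summary(
    table: pd.DataFrame, default_input_fraction: float = 0.1
) -> pd.DataFrame:
    """Per (condition, target) percent-input estimates from a tidy table.

    For each sample the chip_ip Ct is paired with that sample's chip_input
    Ct; replicate percent-input values are aggregated as mean +/- sd with
    a per-target t-test between conditions appended.
    """
    chip = table[table["assay"].isin(["chip_ip", "chip_input"])]
    rows = []
    for (cond, tgt), grp in chip.groupby(["condition", "target"], sort=True):
        ip = grp[grp["assay"] == "chip_ip"].sort_values("sample_id")
        inp = grp[grp["assay"] == "chip_input"].sort_values("sample_id")
        if len(ip) == 0 or len(inp) == 0:
            continue
        if len(ip) != len(inp):
            raise ValueError(
                f"unpaired chip_ip/chip_input rows for {cond}/{tgt}"
            )
        frac = ip["input_fraction"].fillna(default_input_fraction).to_numpy()
        vals = [
            percent_input(ci, cn, f)
            for ci, cn, f in zip(ip["ct"].to_numpy(), inp["ct"].to_numpy(), frac)
        ]
        rows.append(
            {
                "condition": cond,
                "target": tgt,
                "percent_input_mean": float(np.mean(vals)),
                "percent_input_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
                "values": vals,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    # pairwise condition comparison per target, when exactly two conditions
    stars, pvals = [], []
    for _, row in out.iterrows():
        others = out[(out["target"] == row["target"]) & (out["condition"] != row["condition"])]
        if len(others) == 1 and row["n"] >= 2 and others.iloc[0]["n"] >= 2:
            tt = two_sample_ttest(row["values"], others.iloc[0]["values"])
            pvals.append(tt.p)
            stars.append(significance_stars(tt.p))
        else:
            pvals.append(math.nan)
            stars.append("")
    out["p_vs_other"] = pvals
    out["stars"] = stars
    return out.drop(columns=["values"])
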