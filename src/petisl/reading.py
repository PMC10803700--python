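"""Reader-study statistics for paired PET system comparisons.

Given per-lesion, per-reader, per-system detection flags (and SUV readings
when detected), this module computes:

* per-system detection rates on synthetic lesions, whose ground truth is
  known by construction;
* the relative true-positive rate (RTPR) — the ratio of the two systems'
  detection rates on the same lesion set — with a confidence interval from
  the paired 2x2 cross-classification (asymptotic score) or, when pairing
  is unavailable, from the independent-samples Katz log method;
* the natural-lesion reference standard: the union over readers and systems
  of reported natural lesions, whose cardinality is the denominator for
  natural-lesion detection rates;
* inter-observer agreement (IOA): the two readers' concordance rate with an
  exact (Clopper-Pearson) binomial confidence interval, checked against an
  80% adequacy bound;
* a paired-proportions (McNemar-type) sample-size solve for planning.

Human lesion detection itself is out of scope; for end-to-end simulation a
deterministic surrogate reader is provided that detects a lesion when its
peak contrast-to-local-noise ratio exceeds a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InfeasibleError, ValidationError
from .isl import LesionSpec
from .suv import SUVTriple, rd_table
from .volume import Volume3D, sphere_mask

#: Adequacy bound for inter-reader variability.
IOA_ADEQUACY = 0.80


@dataclass
class ReadingRecord:
    """One reader's call on one lesion on one system."""

    lesion_id: str
    reader_id: str
    system: str
    detected: bool
    suv: SUVTriple | None = None

    def __post_init__(self) -> None:
        if self.suv is not None and not self.detected:
            raise ValidationError(
                f"{self.lesion_id}/{self.reader_id}: SUV reported for an undetected lesion"
            )


def consensus(
    records: list[ReadingRecord], rule: str = "and", explicit: bool | None = None
) -> tuple[bool, SUVTriple | None]:
    """Consensus detection flag and SUV for one lesion on one system.

    An externally supplied consensus (the readers' discussed agreement)
    overrides the rule; otherwise the default rule is the conservative AND
    of the readers, with OR available.  The consensus SUV is the per-metric
    mean over the readers who reported one.
    """
    if not records:
        raise ValidationError("consensus requires at least one reading record")
    if rule not in ("and", "or"):
        raise ValidationError(f"unknown consensus rule {rule!r}")
    flags = [r.detected for r in records]
    if explicit is not None:
        if explicit and not any(flags):
            warnings.warn(
                f"{records[0].lesion_id}/{records[0].system}: explicit consensus "
                "is 'detected' but no reader detected the lesion",
                stacklevel=2,
            )
        flag = bool(explicit)
    else:
        flag = all(flags) if rule == "and" else any(flags)
    suvs = [r.suv for r in records if r.suv is not None]
    suv = None
    if flag and suvs:
        suv = SUVTriple(
            suv_max=float(np.mean([s.suv_max for s in suvs])),
            suv_mean=float(np.mean([s.suv_mean for s in suvs])),
            suv_peak=float(np.mean([s.suv_peak for s in suvs])),
        )
    return flag, suv


def natural_reference(records: list[ReadingRecord]) -> set[str]:
    """Union reference standard for natural lesions.

    The set of natural-lesion ids reported by at least one reader on at
    least one system; its cardinality is the natural-lesion denominator.
    """
    return {r.lesion_id for r in records if r.detected}


# ---------------------------------------------------------------------------
# detection tables


@dataclass
class DetectionTable:
    """Per-lesion consensus detection flags for the two systems.

    Backed by a DataFrame with one row per lesion and columns ``lesion_id``,
    ``provenance``, optional strata (``bmi_stratum`` in {"<=25", ">25"},
    ``burden_stratum`` in {"M0", "OligoM", "MultiM"}), plus one boolean
    column ``detected_<system>`` per system.
    """

    df: pd.DataFrame
    systems: tuple[str, str]

    def __post_init__(self) -> None:
        for sys_name in self.systems:
            col = f"detected_{sys_name}"
            if col not in self.df.columns:
                raise ValidationError(f"detection table lacks column {col!r}")

    @classmethod
    def from_counts(
        cls,
        n_total: int,
        detected: dict[str, int],
        provenance: str = "synthetic",
        **strata,
    ) -> "DetectionTable":
        """Table from marginal counts only (no pairing information).

        The flags are laid out with maximal overlap between systems; use it
        for point estimates, not for paired confidence intervals.
        """
        if n_total <= 0:
            raise ValidationError("n_total must be > 0")
        systems = tuple(detected)
        if len(systems) != 2:
            raise ValidationError("exactly two systems expected")
        rows = {"lesion_id": [f"L{i + 1:03d}" for i in range(n_total)],
                "provenance": provenance}
        df = pd.DataFrame(rows)
        for sys_name, k in detected.items():
            if not 0 <= k <= n_total:
                raise ValidationError(f"{sys_name}: count {k} outside [0, {n_total}]")
            df[f"detected_{sys_name}"] = np.arange(n_total) < k
        for key, val in strata.items():
            df[key] = val
        return cls(df=df, systems=systems)

    def filtered(self, **strata) -> pd.DataFrame:
        df = self.df
        for key, val in strata.items():
            if val is None:
                continue
            if key not in df.columns:
                raise ValidationError(f"no stratum column {key!r} in the table")
            df = df[df[key] == val]
        return df

    def cross_classification(self, **strata) -> tuple[int, int, int, int]:
        """Paired 2x2 counts (n11, n10, n01, n00) for (system1, system2)."""
        df = self.filtered(**strata)
        a = df[f"detected_{self.systems[0]}"].to_numpy(bool)
        b = df[f"detected_{self.systems[1]}"].to_numpy(bool)
        return (
            int(np.sum(a & b)),
            int(np.sum(a & ~b)),
            int(np.sum(~a & b)),
            int(np.sum(~a & ~b)),
        )


def detection_rate(
    table: DetectionTable, system: str, **strata
) -> tuple[int, int, float]:
    """(detected, total, proportion) for one system, optionally per stratum."""
    df = table.filtered(**strata)
    if len(df) == 0:
        raise ValidationError("empty stratum: no lesions to evaluate")
    col = f"detected_{system}"
    if col not in df.columns:
        raise ValidationError(f"unknown system {system!r}")
    k = int(df[col].sum())
    n = int(len(df))
    return k, n, k / n


# ---------------------------------------------------------------------------
# ratio of detection rates (RTPR)


@dataclass
class RTPRResult:
    """Ratio of two systems' detection rates with its confidence interval."""

    n: int
    rate_num: float
    rate_den: float
    ratio: float
    ci_low: float | None
    ci_high: float | None
    method: str
    infinite: bool = False

    def rounded(self) -> float:
        """Display convention: ratios to 2 decimals."""
        return round(self.ratio, 2)


def katz_ci(
    x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Katz log confidence interval for a ratio of independent proportions."""
    if min(x1, x2) == 0:
        raise ValidationError("Katz CI undefined with a zero count")
    ratio = (x1 / n1) / (x2 / n2)
    se = np.sqrt(1 / x1 - 1 / n1 + 1 / x2 - 1 / n2)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(ratio * np.exp(-z * se)), float(ratio * np.exp(z * se))


def _paired_score_z(theta: float, n11: int, n10: int, n01: int, n00: int) -> float:
    """Score statistic for H0: p1/p2 = theta on a paired 2x2 table.

    Under H0 the variance of ``x1 - theta*x2`` reduces to
    ``n * theta * (p10 + p01)``; the discordant probabilities are replaced
    by their restricted MLEs obtained numerically.
    """
    n = n11 + n10 + n01 + n00
    x1 = n11 + n10
    x2 = n11 + n01

    def negll(params):
        p11, p01 = params
        p10 = theta * (p11 + p01) - p11
        p00 = 1.0 - p11 - p10 - p01
        p = np.clip(np.array([p11, p10, p01, p00]), 1e-12, None)
        return -(n11 * np.log(p[0]) + n10 * np.log(p[1])
                 + n01 * np.log(p[2]) + n00 * np.log(p[3]))

    # feasible start: shrink the empirical cells toward the constraint
    p11_0 = (n11 + 0.5) / (n + 2)
    p01_0 = (n01 + 0.5) / (n + 2)
    cons = [
        {"type": "ineq", "fun": lambda q: theta * (q[0] + q[1]) - q[0]},  # p10 >= 0
        {"type": "ineq", "fun": lambda q: 1.0 - q[0] - q[1] - (theta * (q[0] + q[1]) - q[0])},
    ]
    res = optimize.minimize(
        negll,
        x0=np.array([p11_0, p01_0]),
        bounds=[(1e-10, 1.0), (1e-10, 1.0)],
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    p11, p01 = res.x
    p10 = max(theta * (p11 + p01) - p11, 1e-12)
    var = n * theta * (p10 + p01)
    return float((x1 - theta * x2) / np.sqrt(var))


def paired_ratio_score_ci(
    n11: int, n10: int, n01: int, n00: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Asymptotic score CI for the ratio of paired proportions.

    Inverts the score test on the 2x2 cross-classification; appropriate when
    both systems read the same lesions, where the Katz interval ignores the
    positive correlation and is conservative.
    """
    x1, x2 = n11 + n10, n11 + n01
    if x1 == 0 or x2 == 0:
        raise ValidationError("paired score CI undefined with a zero marginal count")
    z = stats.norm.ppf(1 - alpha / 2)
    theta_hat = x1 / x2

    def f_low(t):
        return _paired_score_z(t, n11, n10, n01, n00) - z

    def f_high(t):
        return _paired_score_z(t, n11, n10, n01, n00) + z

    lo_bracket, hi_bracket = theta_hat / 100.0, theta_hat * 100.0
    low = optimize.brentq(f_low, lo_bracket, theta_hat, xtol=1e-10)
    high = optimize.brentq(f_high, theta_hat, hi_bracket, xtol=1e-10)
    return float(low), float(high)


def rtpr(
    table: DetectionTable,
    numerator: str | None = None,
    denominator: str | None = None,
    ci_method: str = "auto",
    alpha: float = 0.05,
    **strata,
) -> RTPRResult:
    """Relative true-positive rate: ratio of the two systems' detection rates.

    By default the second system of the table is the numerator (the newer
    scanner) and the first the denominator.  ``ci_method``: ``"paired"``
    (score on the 2x2), ``"katz"`` (independent log), ``"auto"`` (paired,
    falling back to Katz when the paired solve is unavailable) or ``"none"``.
    """
    numerator = numerator or table.systems[1]
    denominator = denominator or table.systems[0]
    k_num, n, p_num = detection_rate(table, numerator, **strata)
    k_den, n_den, p_den = detection_rate(table, denominator, **strata)
    assert n == n_den
    if p_den == 0:
        return RTPRResult(
            n=n, rate_num=p_num, rate_den=0.0, ratio=float("inf"),
            ci_low=None, ci_high=None, method="none", infinite=True,
        )
    ratio = p_num / p_den
    ci_low = ci_high = None
    method = "none"
    if ci_method != "none":
        # cross-classification in (numerator, denominator) order
        df = table.filtered(**strata)
        a = df[f"detected_{numerator}"].to_numpy(bool)
        b = df[f"detected_{denominator}"].to_numpy(bool)
        n11 = int(np.sum(a & b)); n10 = int(np.sum(a & ~b))
        n01 = int(np.sum(~a & b)); n00 = int(np.sum(~a & ~b))
        if ci_method in ("paired", "auto"):
            try:
                ci_low, ci_high = paired_ratio_score_ci(n11, n10, n01, n00, alpha)
                method = "paired-score"
            except (ValidationError, ValueError):
                if ci_method == "paired":
                    raise
        if method == "none" and ci_method in ("katz", "auto"):
            ci_low, ci_high = katz_ci(k_num, n, k_den, n, alpha)
            method = "katz-log"
    return RTPRResult(
        n=n, rate_num=p_num, rate_den=p_den, ratio=ratio,
        ci_low=ci_low, ci_high=ci_high, method=method,
    )


# ---------------------------------------------------------------------------
# inter-observer agreement


@dataclass
class IOAResult:
    """Two-reader concordance with exact binomial confidence interval."""

    n_concordant: int
    n_total: int
    concordance: float
    ci_low: float
    ci_high: float
    adequate: bool  # point estimate above the 80% adequacy bound


def ioa(n_concordant: int, n_total: int, alpha: float = 0.05) -> IOAResult:
    """Concordance rate with Clopper-Pearson exact CI (beta quantiles)."""
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    if not 0 <= n_concordant <= n_total:
        raise ValidationError("n_concordant outside [0, n_total]")
    p = n_concordant / n_total
    lo, hi = proportion_confint(n_concordant, n_total, alpha=alpha, method="beta")
    return IOAResult(
        n_concordant=n_concordant,
        n_total=n_total,
        concordance=p,
        ci_low=float(lo),
        ci_high=float(hi),
        adequate=p > IOA_ADEQUACY,
    )


# ---------------------------------------------------------------------------
# sample size for the paired design


@dataclass
class SampleSizeResult:
    """Solved paired-proportions sample size and its operating point."""

    n: int
    p11: float
    p10: float
    p01: float
    p00: float
    alpha: float
    power: float


def sample_size_paired(
    rtpr_target: float,
    agreement: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> SampleSizeResult:
    """Lesions per group for a McNemar-type paired comparison of two systems.

    Operating-point model: ``agreement`` is the probability that both
    systems detect the lesion (``p11``); every lesion is assumed detectable
    by at least one system (``p00 = 0``), so the discordant probability is
    ``1 - agreement`` and splits so that the detection-rate ratio equals
    ``rtpr_target``.  The returned n uses the Connor (1987) formula for the
    asymptotic McNemar test and should be validated by simulation at the
    same operating point.
    """
    if rtpr_target <= 1:
        raise ValidationError("rtpr_target must be > 1")
    if not (0 < agreement < 1 and 0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("agreement, alpha and power must lie in (0, 1)")
    theta, gamma = rtpr_target, agreement
    if theta * gamma >= 1:
        raise InfeasibleError(
            "operating point infeasible: agreement too high for the target ratio"
        )
    p11, p00 = gamma, 0.0
    p01 = (1.0 - theta * gamma) / (1.0 + theta)
    p10 = 1.0 - gamma - p01
    if p10 <= p01:
        raise InfeasibleError("operating point yields no detectable difference")
    psi = p10 + p01
    d = p10 - p01
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = int(np.ceil((z_a * np.sqrt(psi) + z_b * np.sqrt(psi - d**2)) ** 2 / d**2))
    return SampleSizeResult(
        n=n, p11=p11, p10=p10, p01=p01, p00=p00, alpha=alpha, power=power
    )


def simulate_mcnemar_power(
    n: int,
    probs: tuple[float, float, float, float],
    alpha: float = 0.05,
    n_replicates: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the asymptotic McNemar test at a multinomial point.

    ``probs`` is ``(p11, p10, p01, p00)``; each replicate draws n paired
    lesions and applies the two-sided z-test on the discordant counts.
    """
    rng = np.random.default_rng(seed)
    z_a = stats.norm.ppf(1 - alpha / 2)
    draws = rng.multinomial(n, probs, size=n_replicates)
    n10, n01 = draws[:, 1].astype(float), draws[:, 2].astype(float)
    disc = n10 + n01
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(disc > 0, (n10 - n01) / np.sqrt(disc), 0.0)
    return float(np.mean(np.abs(z) >= z_a))


# ---------------------------------------------------------------------------
# surrogate reader for end-to-end simulation


def detect_lesion(
    vol: Volume3D,
    spec: LesionSpec,
    threshold: float = 12.0,
    signal_margin_mm: float = 2.0,
    shell_inner_margin_mm: float = 8.0,
    shell_width_mm: float = 8.0,
) -> bool:
    """Deterministic surrogate reader: peak contrast-to-local-noise threshold.

    The signal is the maximum voxel in a sphere slightly larger than the
    lesion, referenced to the median of a surrounding background shell.  The
    noise is estimated from first differences of adjacent shell voxels
    (median-absolute-deviation scaled), which is robust to the smooth
    anatomical gradients that otherwise dominate a plain shell SD and mask
    the count-statistics advantage of a more sensitive system.  The lesion
    is called detected when ``(peak - bg_median) / sigma >= threshold``.

    The default threshold is calibrated so that a sub-centimetric lesion at
    the lower end of the design contrast range sits at the detection margin
    on a unit-sensitivity system; the maximum of pure noise over the signal
    region stays several sigma below it.
    """
    r_sig = spec.radius_mm + signal_margin_mm
    sig_mask = sphere_mask(vol, spec.centre_mm, r_sig)
    r_in = spec.radius_mm + shell_inner_margin_mm
    shell = sphere_mask(vol, spec.centre_mm, r_in + shell_width_mm) & ~sphere_mask(
        vol, spec.centre_mm, r_in
    )
    if not sig_mask.any() or shell.sum() < 8:
        raise ValidationError(f"{spec.lesion_id}: reader masks lack support")
    peak = float(vol.data[sig_mask].max())
    bg_median = float(np.median(vol.data[shell]))
    diff = np.diff(vol.data, axis=0) / np.sqrt(2.0)
    shell_pairs = shell[:-1] & shell[1:]
    d = diff[shell_pairs]
    if d.size < 8:
        raise ValidationError(f"{spec.lesion_id}: too few shell voxel pairs")
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d))))
    if sigma == 0:
        return peak > bg_median
    return (peak - bg_median) / sigma >= threshold


# ---------------------------------------------------------------------------
# reading-sheet evaluation


SHEET_COLUMNS = ("lesion_id", "reader_id", "system", "detected")


def evaluate_reading_sheet(
    sheet: pd.DataFrame,
    rule: str = "and",
    alpha: float = 0.05,
    ref_system: str | None = None,
) -> dict:
    """Full statistical evaluation of a reading-session sheet.

    The sheet is long-format with columns ``lesion_id, reader_id, system,
    detected`` plus optional ``suv_max, suv_mean, suv_peak, provenance,
    consensus``.  Returns a report dict with, per provenance class, the
    per-system detection rates and RTPR with CI, per-system IOA, and the RD
    summaries over lesions detected on both systems.
    """
    for col in SHEET_COLUMNS:
        if col not in sheet.columns:
            raise ValidationError(f"reading sheet lacks column {col!r}")
    sheet = sheet.copy()
    if "provenance" not in sheet.columns:
        sheet["provenance"] = "synthetic"
    systems = sorted(sheet["system"].unique())
    if len(systems) != 2:
        raise ValidationError("reading sheet must cover exactly two systems")
    if ref_system is None:
        ref_system = systems[0]
    other_system = next(s for s in systems if s != ref_system)
    has_suv = all(c in sheet.columns for c in ("suv_max", "suv_mean", "suv_peak"))

    def _records(group: pd.DataFrame) -> list[ReadingRecord]:
        recs = []
        for _, row in group.iterrows():
            suv = None
            if has_suv and row["detected"] and np.isfinite(row["suv_max"]):
                suv = SUVTriple(row["suv_max"], row["suv_mean"], row["suv_peak"])
            recs.append(
                ReadingRecord(
                    lesion_id=row["lesion_id"], reader_id=str(row["reader_id"]),
                    system=row["system"], detected=bool(row["detected"]), suv=suv,
                )
            )
        return recs

    # consensus per lesion x system
    cons_rows = []
    for (lesion, sys_name), grp in sheet.groupby(["lesion_id", "system"]):
        explicit = None
        if "consensus" in sheet.columns and grp["consensus"].notna().any():
            explicit = bool(grp["consensus"].iloc[0])
        flag, suv = consensus(_records(grp), rule=rule, explicit=explicit)
        cons_rows.append(
            {
                "lesion_id": lesion,
                "system": sys_name,
                "provenance": grp["provenance"].iloc[0],
                "detected": flag,
                "suv": suv,
            }
        )
    cons = pd.DataFrame(cons_rows)

    report: dict = {"systems": systems, "reference_system": ref_system, "groups": {}}

    for provenance, grp in cons.groupby("provenance"):
        wide = grp.pivot(index="lesion_id", columns="system", values="detected")
        if provenance == "natural":
            # union reference standard over readers and systems
            nat_records = _records(sheet[sheet["provenance"] == "natural"])
            ref_ids = natural_reference(nat_records)
            if not ref_ids:
                report["groups"]["natural"] = {"available": False}
                continue
            wide = wide.loc[sorted(ref_ids)]
        df = wide.reset_index().rename(
            columns={s: f"detected_{s}" for s in systems}
        )
        df["provenance"] = provenance
        table = DetectionTable(df=df, systems=(ref_system, other_system))
        rates = {
            s: dict(zip(("detected", "total", "rate"), detection_rate(table, s)))
            for s in systems
        }
        res = rtpr(table, numerator=other_system, denominator=ref_system, alpha=alpha)
        entry = {
            "available": True,
            "n_lesions": int(len(df)),
            "detection_rates": rates,
            "rtpr": {
                "ratio": res.rounded(),
                "ratio_exact": res.ratio,
                "ci": None if res.ci_low is None
                else [round(res.ci_low, 2), round(res.ci_high, 2)],
                "method": res.method,
                "numerator": other_system,
                "denominator": ref_system,
            },
        }
        # semi-quantitation on lesions detected by consensus on both systems
        both = grp.pivot(index="lesion_id", columns="system", values="suv")
        both = both.dropna()
        if len(both) > 0:
            pairs = [(both.loc[i, ref_system], both.loc[i, other_system]) for i in both.index]
            entry["rd"] = {
                metric: vars(summary) for metric, summary in rd_table(pairs).items()
            }
            entry["rd"]["n"] = int(len(both))
        report["groups"][provenance] = entry

    # IOA per system over all lesions with >= 2 readers
    report["ioa"] = {}
    for sys_name, grp in sheet.groupby("system"):
        wide = grp.pivot_table(
            index="lesion_id", columns="reader_id", values="detected", aggfunc="first"
        )
        readers = list(wide.columns)
        if len(readers) < 2:
            continue
        complete = wide.dropna()
        concordant = int((complete[readers[0]] == complete[readers[1]]).sum())
        res = ioa(concordant, len(complete), alpha=alpha)
        report["ioa"][sys_name] = {
            "concordant": res.n_concordant,
            "total": res.n_total,
            "concordance_pct": round(res.concordance * 100, 1),
            "ci_pct": [round(res.ci_low * 100, 1), round(res.ci_high * 100, 1)],
            "adequate": res.adequate,
        }
    return report


def demo_reading_sheet(seed: int = 20240122) -> pd.DataFrame:
    """A worked two-reader, two-system reading sheet for 60 synthetic lesions.

    Encodes a consensus of 59/60 detections on the TOF system and 33/60 on
    the non-TOF system (explicit consensus column), reader concordances of
    53/60 and 52/60, and SUV readings biased higher on the TOF system.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = 60
    ids = [f"L{i + 1:03d}" for i in range(n)]
    rows = []
    layouts = {
        # system: (reader1 detections, reader2 detections, consensus detections)
        # reader sets are nested prefixes, so concordant = 60 - |k1 - k2|;
        # the consensus set stays within reader 1's detections
        "DMI-like": (59, 52, 59),  # concordant 53
        "DIQ-like": (37, 29, 33),  # concordant 52
    }
    for sys_name, (k1, k2, kc) in layouts.items():
        hotter = 1.5 if sys_name == "DMI-like" else 1.0
        base = rng.uniform(2.0, 8.0, size=n) * hotter
        for reader, k in (("R1", k1), ("R2", k2)):
            for i, lesion in enumerate(ids):
                detected = i < k
                suv_max = base[i] * rng.uniform(0.95, 1.05) if detected else np.nan
                rows.append(
                    {
                        "lesion_id": lesion,
                        "reader_id": reader,
                        "system": sys_name,
                        "detected": detected,
                        "suv_max": suv_max,
                        "suv_mean": suv_max * rng.uniform(0.7, 0.9) if detected else np.nan,
                        "suv_peak": suv_max * rng.uniform(0.55, 0.8) if detected else np.nan,
                        "provenance": "synthetic",
                        "consensus": ids.index(lesion) < kc,
                    }
                )
    return pd.DataFrame(rows)
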