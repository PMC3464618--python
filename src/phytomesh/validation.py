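"""Agreement statistics between automated and reference measurements.

For paired measurements (a_i automated, m_i reference) the suite computes
the mean absolute percentage error E = 100 * mean(|a - m| / m), RMSE, the
mean bias error MBE = mean(a - m) (systematic over/under-estimation), the
sample standard deviation of the relative errors, trimmed variants that
drop the best and worst 5% of relative errors, the squared Pearson
correlation R^2, the two-way random-effects absolute-agreement
single-measures intraclass correlation ICC(2,1), and a Bland-Altman-style
scatter of relative error against log10 of the pair mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MeasurementPairs:
    """Paired automated/reference values for one parameter.

    NA pairs are excluded on construction; the count is kept. The reference
    must be strictly positive (relative errors divide by it).
    """

    parameter: str
    automated: np.ndarray
    reference: np.ndarray
    provenance: list = field(default_factory=list)  # one key per pair, for tie-breaks
    n_excluded: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.automated, dtype=float)
        m = np.asarray(self.reference, dtype=float)
        if a.shape != m.shape:
            raise ValueError("automated and reference must have equal length")
        if not self.provenance:
            self.provenance = list(range(len(a)))
        ok = np.isfinite(a) & np.isfinite(m)
        self.n_excluded += int((~ok).sum())
        self.automated = a[ok]
        self.reference = m[ok]
        self.provenance = [p for p, keep in zip(self.provenance, ok) if keep]
        if (self.reference <= 0).any():
            raise ValueError("reference measurements must be positive")

    def __len__(self) -> int:
        return len(self.automated)


@dataclass
class AgreementReport:
    parameter: str
    n: int
    mape: float  # %
    mean_abs_error_mm: float
    sigma: float  # % — sample sd of the relative errors
    mape_trimmed: float
    sigma_trimmed: float
    r2: float
    icc: float
    rmse: float
    mbe: float
    n_excluded: int = 0

    def to_row(self) -> dict:
        return {
            "parameter": self.parameter, "n": self.n, "mape_pct": self.mape,
            "mean_abs_error_mm": self.mean_abs_error_mm, "sigma_pct": self.sigma,
            "mape_trimmed_pct": self.mape_trimmed, "sigma_trimmed_pct": self.sigma_trimmed,
            "r2": self.r2, "icc": self.icc, "rmse_mm": self.rmse, "mbe_mm": self.mbe,
            "n_excluded": self.n_excluded,
        }


def relative_error(a, m):
    """|a - m| / m (dimensionless); the reference m must be positive."""
    a = np.asarray(a, dtype=float)
    m = np.asarray(m, dtype=float)
    if (m <= 0).any():
        raise ValueError("reference measurement must be positive")
    return np.abs(a - m) / m


def error_summary(pairs: MeasurementPairs, trim_fraction: float = 0.05) -> dict:
    """MAPE (%), RMSE, MBE, sd of relative errors and 10%-trimmed variants.

    Trimming drops floor(trim_fraction * n) pairs at each tail of the
    relative-error distribution (ties broken on the provenance key).
    """
    n = len(pairs)
    if n < 1:
        raise ValueError("no pairs")
    a, m = pairs.automated, pairs.reference
    eps = relative_error(a, m)
    diff = a - m
    out = {
        "n": n,
        "mape": float(100.0 * eps.mean()),
        "mean_abs_error_mm": float(np.abs(diff).mean()),
        "rmse": float(np.sqrt((diff ** 2).mean())),
        "mbe": float(diff.mean()),
        "sigma": float(np.std(100.0 * eps, ddof=1)) if n >= 2 else float("nan"),
    }
    k = int(np.floor(trim_fraction * n))
    order = sorted(range(n), key=lambda i: (eps[i], str(pairs.provenance[i])))
    keep = order[k: n - k] if k > 0 else order
    te = eps[keep]
    out["n_trimmed"] = len(keep)
    out["mape_trimmed"] = float(100.0 * te.mean())
    out["sigma_trimmed"] = float(np.std(100.0 * te, ddof=1)) if len(keep) >= 2 else float("nan")
    return out


def pearson_r2(pairs: MeasurementPairs) -> float:
    """Square of the sample Pearson product-moment correlation."""
    a, m = pairs.automated, pairs.reference
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(m) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(a, m)[0, 1] ** 2)


def icc_2_1(pairs: MeasurementPairs) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    From the two-way ANOVA with n subjects and k = 2 raters (automated,
    reference): (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    Returns NaN for a degenerate ANOVA (no between-subject variance).
    """
    x = np.column_stack([pairs.automated, pairs.reference])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr <= 1e-300 and mse <= 1e-300 and msc <= 1e-300):
        return float("nan")
    return float((msr - mse) / denom)


def bland_altman_points(pairs: MeasurementPairs) -> tuple[np.ndarray, int]:
    """(x, y) points with x = log10 of the pair mean and y the relative
    error; pairs with non-positive mean are excluded (count returned)."""
    a, m = pairs.automated, pairs.reference
    mean = 0.5 * (a + m)
    ok = mean > 0
    x = np.log10(mean[ok])
    y = relative_error(a[ok], m[ok])
    return np.column_stack([x, y]), int((~ok).sum())


JOIN_KEYS = ["plant", "timepoint", "organ_type", "organ_index", "parameter"]


def validation_report(
    auto: pd.DataFrame,
    ref: pd.DataFrame,
    join_keys: list[str] | None = None,
    trim_fraction: float = 0.05,
) -> tuple[dict[str, AgreementReport], pd.DataFrame]:
    """Join automated and reference long-format tables and compute one
    agreement report per parameter.

    Both tables need the join keys plus a ``value`` column. An ambiguous
    join (duplicate keys) raises with the offending rows listed; unmatched
    and NA rows are excluded and counted.
    """
    keys = join_keys or JOIN_KEYS
    for name, df in (("auto", auto), ("ref", ref)):
        dup = df.duplicated(subset=keys, keep=False)
        if dup.any():
            raise ValueError(f"ambiguous join in {name} table:\n{df[dup][keys]}")
    merged = auto.merge(ref, on=keys, suffixes=("_auto", "_ref"))
    reports: dict[str, AgreementReport] = {}
    rows = []
    for param, grp in merged.groupby("parameter", sort=True):
        a = grp["value_auto"].to_numpy(dtype=float)
        m = grp["value_ref"].to_numpy(dtype=float)
        prov = list(zip(*[grp[c] for c in keys[:-1]]))
        good = np.isfinite(m) & (m > 0)
        pairs = MeasurementPairs(param, a[good], m[good],
                                 [p for p, g in zip(prov, good) if g],
                                 n_excluded=int((~good).sum()))
        if len(pairs) < 3:
            continue
        s = error_summary(pairs, trim_fraction)
        reports[param] = AgreementReport(
            parameter=param, n=s["n"], mape=s["mape"],
            mean_abs_error_mm=s["mean_abs_error_mm"], sigma=s["sigma"],
            mape_trimmed=s["mape_trimmed"], sigma_trimmed=s["sigma_trimmed"],
            r2=pearson_r2(pairs), icc=icc_2_1(pairs), rmse=s["rmse"], mbe=s["mbe"],
            n_excluded=pairs.n_excluded,
        )
        rows.append(reports[param].to_row())
    return reports, pd.DataFrame(rows)
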