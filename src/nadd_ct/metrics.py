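"""Image-quality metrics and paired significance testing.

SSIM and PSNR are computed with scikit-image on a *fixed* evaluation dynamic
range (2000 HU by default) so that scores are comparable across slices; VIF
is the pixel-domain visual information fidelity (four Gaussian scales,
scale-mixture variance partition, sensor noise sigma_n^2 = 2 on the
normalized 8-bit-equivalent range), implemented here directly from its
closed form. Arm comparisons use the one-sided Wilcoxon signed-rank test at
significance level alpha = 1%: exact enumeration of the signed-rank null for
up to 25 nonzero differences (mid-ranked ties included), a normal
approximation with continuity and tie correction beyond that.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm
from skimage.metrics import structural_similarity

from .containers import ImageSlice

#: Fixed evaluation dynamic range in HU (covers soft-tissue/lung windows).
EVAL_RANGE_HU = 2000.0


def _pixels(a) -> np.ndarray:
    return np.asarray(a.pixels if isinstance(a, ImageSlice) else a, dtype=np.float64)


def psnr(a, ref, peak: float = EVAL_RANGE_HU) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE), in dB.

    Identical images give +inf (flagged, not raised).
    """
    x, r = _pixels(a), _pixels(ref)
    if x.shape != r.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {r.shape}")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((x - r) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * math.log10(peak**2 / mse)


def ssim(a, ref, data_range: float = EVAL_RANGE_HU, win_size: int = 11, sigma: float = 1.5) -> float:
    """Mean local SSIM with an 11x11 Gaussian window (sigma = 1.5).

    Constants K1 = 0.01, K2 = 0.03 on the declared dynamic range.
    """
    x, r = _pixels(a), _pixels(ref)
    if x.shape != r.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {r.shape}")
    if win_size > min(x.shape):
        raise ValueError(f"window size {win_size} exceeds image extent {x.shape}")
    return float(
        structural_similarity(
            r,
            x,
            data_range=data_range,
            gaussian_weights=True,
            sigma=sigma,
            win_size=win_size,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def vif(a, ref, data_range: float = EVAL_RANGE_HU, sigma_nsq: float = 2.0) -> float:
    """Pixel-domain visual information fidelity (VIFp).

    Both images are mapped to the conventional 8-bit-equivalent scale
    (0..255 over ``data_range``) on which the sensor-noise variance
    sigma_n^2 = 2 is calibrated. Returns 1 for identical inputs and
    decreases under noise or blur. A constant reference carries no
    information; that degenerate case raises ValueError.
    """
    x, r = _pixels(a), _pixels(ref)
    if x.shape != r.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {r.shape}")
    if np.ptp(r) == 0:
        raise ValueError("VIF is undefined for a constant (zero-variance) reference")
    scale = 255.0 / data_range
    r = r * scale
    x = x * scale

    num = 0.0
    den = 0.0
    for level in range(1, 5):
        sd = (2 ** (4 - level + 1) + 1) / 5.0
        if level > 1:
            r = gaussian_filter(r, sd)[::2, ::2]
            x = gaussian_filter(x, sd)[::2, ::2]
        mu1 = gaussian_filter(r, sd)
        mu2 = gaussian_filter(x, sd)
        s1 = gaussian_filter(r * r, sd) - mu1 * mu1
        s2 = gaussian_filter(x * x, sd) - mu2 * mu2
        s12 = gaussian_filter(r * x, sd) - mu1 * mu2
        s1 = np.maximum(s1, 0.0)
        s2 = np.maximum(s2, 0.0)

        g = s12 / (s1 + 1e-10)
        sv = s2 - g * s12
        g = np.where(s1 < 1e-10, 0.0, g)
        sv = np.where(s1 < 1e-10, s2, sv)
        sv = np.where(s2 < 1e-10, 0.0, sv)
        g = np.where(s2 < 1e-10, 0.0, g)
        sv = np.where(g < 0.0, s2, sv)
        g = np.maximum(g, 0.0)
        sv = np.maximum(sv, 1e-10)

        num += float(np.sum(np.log10(1.0 + g * g * s1 / (sv + sigma_nsq))))
        den += float(np.sum(np.log10(1.0 + s1 / sigma_nsq)))
    return num / den


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank, one-sided
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    """One-sided signed-rank test outcome (alternative: median difference > 0)."""

    p: float
    statistic: float  # W+ (sum of positive ranks)
    n_effective: int  # nonzero differences used
    method: str  # 'exact' or 'approx'

    def significant(self, alpha: float = 0.01) -> bool:
        return self.p < alpha


EXACT_MAX_N = 25


def wilcoxon_one_sided(differences: Iterable[float]) -> WilcoxonResult:
    """One-sided Wilcoxon signed-rank test for paired differences.

    Zeros are dropped, tied absolute values are mid-ranked. For up to
    25 nonzero differences the p-value comes from exact enumeration of the
    2^n sign-assignment null (dynamic program over doubled integer ranks);
    beyond that, a normal approximation with continuity correction and tie
    correction of the variance. The alternative is 'differences tend to be
    positive', so five positive differences out of five give p = 1/32.
    """
    d = np.asarray(list(differences), dtype=np.float64)
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: the signed-rank test is undefined")
    if n < 5:
        raise ValueError(f"need at least 5 nonzero differences, got {n}")

    abs_d = np.abs(d)
    order = np.argsort(abs_d, kind="stable")
    ranks = np.empty(n)
    sorted_abs = abs_d[order]
    # mid-ranks for ties
    i = 0
    pos = 1
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (pos + (pos + (j - i))) / 2.0
        pos += j - i + 1
        i = j + 1
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_MAX_N:
        # doubled ranks are exact integers even with mid-ranked ties
        r2 = np.rint(2.0 * ranks).astype(np.int64)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: counts.size - r]
        w2 = int(round(2.0 * w_plus))
        p = float(counts[w2:].sum() / 2.0**n)
        return WilcoxonResult(p=p, statistic=w_plus, n_effective=n, method="exact")

    mean = n * (n + 1) / 4.0
    # variance with tie correction: sum(r^2) formulation handles mid-ranks
    var = float(np.sum(ranks**2)) / 4.0
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return WilcoxonResult(
        p=float(norm.sf(z)), statistic=w_plus, n_effective=n, method="approx"
    )


# ---------------------------------------------------------------------------
# per-slice metric bookkeeping
# ---------------------------------------------------------------------------

METRIC_NAMES = ("ssim", "psnr", "vif")


@dataclass
class SliceRecord:
    arm: str
    subject_id: str
    slice_id: str
    ssim: float
    psnr: float
    vif: float


@dataclass
class Comparison:
    arm_a: str
    arm_b: str
    metric: str
    p_value: float
    significant_at_1pct: bool
    n: int
    method: str


@dataclass
class MetricsReport:
    """Per-slice metric records plus arm-level aggregation and comparisons.

    Arm means are always recomputed from the per-slice records, never cached,
    so a report regenerated from stored predictions is bit-identical.
    """

    records: list[SliceRecord] = field(default_factory=list)
    comparisons: list[Comparison] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def add(self, arm: str, subject_id: str, slice_id: str, a, ref) -> SliceRecord:
        rec = SliceRecord(
            arm=arm,
            subject_id=subject_id,
            slice_id=slice_id,
            ssim=ssim(a, ref),
            psnr=psnr(a, ref),
            vif=vif(a, ref),
        )
        self.records.append(rec)
        return rec

    def arms(self) -> list[str]:
        return sorted({r.arm for r in self.records})

    def per_slice(self, arm: str, metric: str) -> dict[str, float]:
        """slice_id -> value for one arm/metric (sorted by slice_id)."""
        vals = {r.slice_id: getattr(r, metric) for r in self.records if r.arm == arm}
        return dict(sorted(vals.items()))

    def arm_means(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for arm in self.arms():
            rows = [r for r in self.records if r.arm == arm]
            out[arm] = {m: float(np.mean([getattr(r, m) for r in rows])) for m in METRIC_NAMES}
        return out

    def compare(self, arm_a: str, arm_b: str, metric: str) -> Comparison:
        """Test 'arm_a metric > arm_b metric' on paired per-slice values."""
        va = self.per_slice(arm_a, metric)
        vb = self.per_slice(arm_b, metric)
        common = sorted(set(va) & set(vb))
        if not common:
            raise ValueError(f"no paired slices between {arm_a!r} and {arm_b!r}")
        diffs = [va[s] - vb[s] for s in common]
        res = wilcoxon_one_sided(diffs)
        comp = Comparison(
            arm_a=arm_a,
            arm_b=arm_b,
            metric=metric,
            p_value=res.p,
            significant_at_1pct=res.significant(0.01),
            n=res.n_effective,
            method=res.method,
        )
        self.comparisons.append(comp)
        return comp

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "schema": "nadd-ct/metrics-report/v1",
            "metadata": self.metadata,
            "records": [asdict(r) for r in self.records],
            "arm_means": self.arm_means(),
            "comparisons": [asdict(c) for c in self.comparisons],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["arm", "subject_id", "slice_id", *METRIC_NAMES])
            for r in self.records:
                writer.writerow([r.arm, r.subject_id, r.slice_id, r.ssim, r.psnr, r.vif])

    @classmethod
    def from_json(cls, path) -> "MetricsReport":
        with open(path) as fh:
            payload = json.load(fh)
        rep = cls(metadata=payload.get("metadata", {}))
        rep.records = [SliceRecord(**r) for r in payload["records"]]
        rep.comparisons = [Comparison(**c) for c in payload.get("comparisons", [])]
        return rep
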