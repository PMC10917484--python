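"""Quantitative stack comparison: quality metrics, byte diffs, line profiles.

Quality metrics follow the conventions of the Fiji SNR plugin, computed per
frame and then aggregated as mean ± SD over frames:

    MSE  = sum((r - t)^2) / N          RMSE = sqrt(MSE)
    MAE  = sum(|r - t|) / N
    SNR  = 10 log10( sum(r^2) / sum((r - t)^2) )          [dB]
    PSNR = 10 log10( max(r)^2 / MSE )                     [dB]

The PSNR peak is the maximum of the REFERENCE frame (the stacks are float
valued, so no fixed bit-depth peak applies).  Identical frames have zero
error and SNR/PSNR are reported as a +infinity sentinel ("inf" in
serialized output).

Byte-level comparison exposes the signature of pure precision differences:
two binary32 stacks differing only in low-order mantissa bits show differing
bytes recurring within 4-byte words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np

from .exceptions import ShapeMismatchError
from .stacks import PRECISION_DTYPES, ImageStack

#: Formula strings embedded in serialized reports so the exact definitions
#: used are auditable alongside the numbers.
METRIC_FORMULAS = {
    "rmse": "sqrt(sum((ref-test)^2)/N) per frame",
    "mae": "sum(|ref-test|)/N per frame",
    "snr_db": "10*log10(sum(ref^2)/sum((ref-test)^2)) per frame",
    "psnr_db": "10*log10(max(ref)^2/MSE) per frame, peak = max of reference frame",
    "aggregation": "per-frame values, then mean +/- SD over frames",
}


@dataclass(frozen=True)
class FrameQuality:
    frame: int  # 1-based
    rmse: float
    mae: float
    snr_db: float  # +inf when error is exactly zero; nan when ref frame all-zero
    psnr_db: float


@dataclass(frozen=True)
class QualityReport:
    frames: tuple[FrameQuality, ...] = field(repr=False)
    rmse_mean: float = 0.0
    rmse_sd: float = 0.0
    mae_mean: float = 0.0
    mae_sd: float = 0.0
    snr_mean_db: float = 0.0
    snr_sd_db: float = 0.0
    psnr_mean_db: float = 0.0
    psnr_sd_db: float = 0.0

    def as_dict(self) -> dict:
        def ser(x: float):
            if np.isposinf(x):
                return "inf"
            if np.isnan(x):
                return "undefined"
            return float(x)

        return {
            "formulas": METRIC_FORMULAS,
            "rmse": {"mean": ser(self.rmse_mean), "sd": ser(self.rmse_sd)},
            "mae": {"mean": ser(self.mae_mean), "sd": ser(self.mae_sd)},
            "snr_db": {"mean": ser(self.snr_mean_db), "sd": ser(self.snr_sd_db)},
            "psnr_db": {"mean": ser(self.psnr_mean_db), "sd": ser(self.psnr_sd_db)},
            "frames": [
                {
                    "frame": f.frame,
                    "rmse": ser(f.rmse),
                    "mae": ser(f.mae),
                    "snr_db": ser(f.snr_db),
                    "psnr_db": ser(f.psnr_db),
                }
                for f in self.frames
            ],
        }


def quality(ref: ImageStack, test: ImageStack) -> QualityReport:
    """Per-frame SNR/PSNR/RMSE/MAE of ``test`` against ``ref``, then mean±SD.

    RMSE/MAE are symmetric under swapping ref and test; SNR/PSNR are not
    (both normalize by the reference).  A frame whose reference is all-zero
    has undefined SNR (reported as NaN and excluded from the aggregate).
    """
    if ref.shape != test.shape:
        raise ShapeMismatchError(f"ref {ref.shape} vs test {test.shape}")
    r64 = ref.data.astype(np.float64)
    t64 = test.data.astype(np.float64)
    frames = []
    for k in range(ref.n_frames):
        r = r64[:, :, k]
        t = t64[:, :, k]
        err = r - t
        sse = float(np.sum(err * err))
        n = err.size
        mse = sse / n
        rmse = float(np.sqrt(mse))
        mae = float(np.sum(np.abs(err)) / n)
        ref_power = float(np.sum(r * r))
        peak = float(np.max(r))
        if sse == 0.0:
            snr = np.inf
            psnr = np.inf
        else:
            snr = 10.0 * np.log10(ref_power / sse) if ref_power > 0 else np.nan
            psnr = 10.0 * np.log10(peak * peak / mse) if peak > 0 else np.nan
        frames.append(FrameQuality(frame=k + 1, rmse=rmse, mae=mae,
                                   snr_db=snr, psnr_db=psnr))

    def agg(values):
        arr = np.asarray([v for v in values if not np.isnan(v)], dtype=np.float64)
        if arr.size == 0:
            return np.nan, np.nan
        if np.isposinf(arr).any():
            return np.inf, np.nan if np.isposinf(arr).all() else np.inf
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    rmse_m, rmse_s = agg([f.rmse for f in frames])
    mae_m, mae_s = agg([f.mae for f in frames])
    snr_m, snr_s = agg([f.snr_db for f in frames])
    psnr_m, psnr_s = agg([f.psnr_db for f in frames])
    return QualityReport(
        frames=tuple(frames),
        rmse_mean=rmse_m, rmse_sd=rmse_s,
        mae_mean=mae_m, mae_sd=mae_s,
        snr_mean_db=snr_m, snr_sd_db=snr_s,
        psnr_mean_db=psnr_m, psnr_sd_db=psnr_s,
    )


@dataclass(frozen=True)
class ByteDiffReport:
    total_bytes: int
    n_differing_bytes: int
    structurally_different: bool = False
    #: counts of differing bytes by (offset mod 4); for binary32 payloads
    #: differing only in low-order mantissa bits, the mass concentrates in
    #: the low-order byte positions of each 4-byte word.
    stride_histogram: tuple[int, int, int, int] = (0, 0, 0, 0)
    first_offsets: tuple[int, ...] = field(default=(), repr=False)

    @property
    def identical(self) -> bool:
        return not self.structurally_different and self.n_differing_bytes == 0

    def as_dict(self) -> dict:
        return {
            "total_bytes": self.total_bytes,
            "n_differing_bytes": self.n_differing_bytes,
            "structurally_different": self.structurally_different,
            "stride_histogram_mod4": list(self.stride_histogram),
            "first_offsets": list(self.first_offsets),
        }


def byte_compare(a: bytes, b: bytes, max_offsets: int = 64) -> ByteDiffReport:
    """Exact byte-by-byte diff of two stored payloads.

    Equal lengths are compared offset by offset; unequal lengths are
    reported as structurally different without crashing.  The histogram of
    differing offsets modulo 4 exposes the every-4-bytes pattern produced by
    float32 values differing in their final mantissa bits.
    """
    if len(a) != len(b):
        return ByteDiffReport(
            total_bytes=max(len(a), len(b)),
            n_differing_bytes=abs(len(a) - len(b)),
            structurally_different=True,
        )
    av = np.frombuffer(a, dtype=np.uint8)
    bv = np.frombuffer(b, dtype=np.uint8)
    diff_offsets = np.nonzero(av != bv)[0]
    hist = [0, 0, 0, 0]
    if diff_offsets.size:
        mod = diff_offsets % 4
        for m in range(4):
            hist[m] = int(np.count_nonzero(mod == m))
    return ByteDiffReport(
        total_bytes=len(a),
        n_differing_bytes=int(diff_offsets.size),
        stride_histogram=tuple(hist),
        first_offsets=tuple(int(o) for o in diff_offsets[:max_offsets]),
    )


def byte_compare_stacks(ref: ImageStack, test: ImageStack) -> ByteDiffReport:
    """Byte diff of the raw in-memory payloads of two stacks."""
    return byte_compare(ref.data.tobytes(), test.data.tobytes())


@dataclass(frozen=True)
class LineProfile:
    frame: int  # 1-based
    row: int  # 1-based
    positions: tuple[int, ...]
    values: tuple[float, ...]

    def to_csv(self) -> str:
        lines = ["position,value"]
        lines += [f"{p},{v!r}" for p, v in zip(self.positions, self.values)]
        return "\n".join(lines) + "\n"


def line_profile(stack: ImageStack, frame: int, row: int | None = None) -> LineProfile:
    """Intensities along one full row of one frame (both 1-based).

    The default row is the center row, ceil(n_rows / 2) — the full-width
    central transect conventionally used to compare reconstructions.
    """
    img = stack.frame(frame)  # validates the 1-based frame index
    n_rows = img.shape[0]
    if row is None:
        row = (n_rows + 1) // 2  # 1-based ceil(n/2)
    if not 1 <= row <= n_rows:
        raise IndexError(f"row {row} out of range 1..{n_rows} (rows are 1-based)")
    vals = img[row - 1, :]
    return LineProfile(
        frame=frame,
        row=row,
        positions=tuple(range(1, len(vals) + 1)),
        values=tuple(float(v) for v in vals),
    )


def float_repr(decimal_text: str, precision: str) -> str:
    """Exact decimal expansion of the nearest binary32/binary64 value.

    IEEE-754 stores only dyadic rationals, so every stored value has a
    finite (if long) exact decimal expansion; e.g. the nearest binary32 to
    "0.3" is exactly 0.300000011920928955078125.
    """
    if precision not in PRECISION_DTYPES:
        raise ValueError(f"precision must be one of {sorted(PRECISION_DTYPES)}")
    try:
        if precision == "binary32":
            value = float(np.float32(decimal_text))  # widening float32->float64 is exact
        else:
            value = float(decimal_text)
    except (ValueError, OverflowError) as exc:
        raise ValueError(f"cannot parse {decimal_text!r} as a finite decimal") from exc
    if not np.isfinite(value):
        raise ValueError(f"{decimal_text!r} does not round to a finite value")
    d = Decimal(value)  # exact binary-to-decimal conversion
    text = format(d, "f")
    if "." in text:
        text = text.rstrip("0").rstrip(".") or "0"
    return text
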