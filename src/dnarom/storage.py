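"""Image-storage benchmark: bit-load dependent read accuracy and power.

An image is binarized into a bit matrix, loaded onto a crossbar (logic 1 =
the higher-conductance species), read row by row, and reconstructed with the
optimal threshold; the figure of merit is the bit error rate as a function
of the image's *bit load* (the percentage of logic-1 cells) for different
array sizes and interconnect resistances, together with the average read
power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossbar import CrossbarSpec, readout_map
from .montecarlo import optimal_threshold
from .transport import IVTable

__all__ = ["ImageJob", "image_to_bits", "evaluate_storage"]


@dataclass
class ImageJob:
    """One bit matrix destined for an array, with its provenance."""

    bits: np.ndarray
    bit_load: float   # percentage of logic-1 cells
    source: str = ""

    def __post_init__(self):
        self.bits = np.asarray(self.bits)
        if not (0.0 <= self.bit_load <= 100.0):
            raise ValueError("bit_load must be a percentage")


def image_to_bits(
    image: np.ndarray,
    m: int,
    n: int,
    binarization: str = "midgray",
    source: str = "",
) -> ImageJob:
    """Binarize a grayscale image into an ``m x n`` bit matrix.

    Images larger than the array are center-cropped first (deterministic);
    smaller images are rejected.  ``binarization="midgray"`` thresholds at
    the middle of the image dtype's dynamic range (0.5 for float images,
    127.5 for 8-bit) — the rule the synthetic benchmark images are built
    for; ``"median"`` thresholds at the (whole-image) median instead.  The
    bit load is ``100 * (#ones) / (m n)``.
    """
    img = np.asarray(image)
    if img.ndim == 3:  # RGB(A): luminance average
        img = img[..., :3].mean(axis=2)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale (or RGB)")
    if img.shape[0] < m or img.shape[1] < n:
        raise ValueError(f"image {img.shape} smaller than array ({m}, {n})")
    r0 = (img.shape[0] - m) // 2
    c0 = (img.shape[1] - n) // 2
    full = img.astype(float)
    crop = full[r0 : r0 + m, c0 : c0 + n]
    if binarization == "midgray":
        thresh = 127.5 if np.issubdtype(img.dtype, np.integer) else 0.5
    elif binarization == "median":
        thresh = float(np.median(full))
    else:
        raise ValueError(f"unknown binarization {binarization!r}")
    bits = (crop > thresh).astype(np.int8)
    return ImageJob(
        bits=bits, bit_load=100.0 * float(bits.mean()), source=source
    )


def evaluate_storage(
    images: list[np.ndarray],
    sizes: list[int],
    r_int_list: list[float],
    iv0: IVTable,
    iv1: IVTable,
    v_in: float = 1.0,
    binarization: str = "midgray",
    solver: str = "kirchhoff",
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BER-vs-bit-load and power tables over array size and R_int.

    Every image is loaded onto every (square) array size at every
    interconnect resistance; each job is read row by row, thresholded per
    array, and grouped by integer-rounded bit load.  Returns two tidy
    frames: ``(size, r_int_ohm, job_id, bit_load_pct, bit_load_bin,
    ber_pct)`` and ``(size, r_int_ohm, power_W)`` (mean Kirchhoff power over
    jobs and row reads).
    """
    if not images:
        raise ValueError("no images given")
    ber_rows = []
    power_rows = []
    for size in sizes:
        jobs = [
            image_to_bits(img, size, size, binarization=binarization, source=str(k))
            for k, img in enumerate(images)
        ]
        for r_int in r_int_list:
            powers = []
            for job_id, job in enumerate(jobs):
                spec = CrossbarSpec(
                    bits=job.bits, iv0=iv0, iv1=iv1, r_int=r_int, v_in=v_in
                )
                rm = readout_map(spec, solver=solver, tol=tol)
                c0 = rm.I_out[job.bits == 0]
                c1 = rm.I_out[job.bits == 1]
                if c0.size and c1.size:
                    _, ber = optimal_threshold(c0, c1)
                else:  # degenerate all-0 / all-1 image: nothing to confuse
                    ber = 0.0
                ber_rows.append(
                    {
                        "size": size,
                        "r_int_ohm": r_int,
                        "job_id": job_id,
                        "bit_load_pct": job.bit_load,
                        "bit_load_bin": int(round(job.bit_load)),
                        "ber_pct": ber,
                    }
                )
                if solver == "kirchhoff":
                    powers.append(rm.mean_power)
            if powers:
                power_rows.append(
                    {
                        "size": size,
                        "r_int_ohm": r_int,
                        "power_W": float(np.mean(powers)),
                    }
                )
    return pd.DataFrame(ber_rows), pd.DataFrame(power_rows)
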