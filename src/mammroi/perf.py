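"""Analytic compute/transfer performance model of the streaming design.

Two terms bound a run.  Processing time is

    T_processing = cycles / frequency,

with one cycle per pixel per kernel pass (the streaming kernels consume one
pixel per tick), and PCIe transfer time is

    T_PCIe = max(BytesIn / BandwidthIn, BytesOut / BandwidthOut).

With k parallel kernel graphs (k <= 8, the stream limit) the image batch is
split into ceil(n/k) sequential waves, so the processing term shrinks with
k while the transfer term — the whole byte volume over a shared bus — does
not.  The total models full overlap of compute and transfer,
``max(T_processing, T_PCIe)``: once the transfer term dominates, adding
kernels buys nothing, which is the bandwidth-saturation plateau.  Pixels
travel as 32-bit words, so 4 bytes/pixel each way by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "PerfScenario",
    "processing_time",
    "pcie_time",
    "total_time",
    "saturation_point",
    "sweep_kernels",
    "report_table",
]

MAX_KERNELS = 8
BYTES_PER_PIXEL = 4


def processing_time(cycles: int, frequency: float) -> float:
    """Seconds to clock ``cycles`` ticks at ``frequency`` Hz: cycles/frequency."""
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency!r}")
    if cycles < 0:
        raise ValueError("cycles must be nonnegative")
    return cycles / frequency


def pcie_time(bytes_in: int, bandwidth_in: float, bytes_out: int, bandwidth_out: float) -> float:
    """Transfer seconds: max of the in- and out-direction byte/bandwidth ratios."""
    if bandwidth_in <= 0 or bandwidth_out <= 0:
        raise ValueError("bandwidths must be positive")
    if bytes_in < 0 or bytes_out < 0:
        raise ValueError("byte counts must be nonnegative")
    return max(bytes_in / bandwidth_in, bytes_out / bandwidth_out)


@dataclass(frozen=True)
class PerfScenario:
    """One modeled configuration.

    ``cycles`` is per image per kernel pass (rows*cols for a one-pixel-per-
    tick kernel); byte counts are per image per direction.
    """

    cycles: int
    frequency: float
    bytes_in: int
    bytes_out: int
    bandwidth_in: float
    bandwidth_out: float
    n_images: int = 1
    kernels_k: int = 1

    def __post_init__(self) -> None:
        if self.cycles <= 0 or self.n_images <= 0:
            raise ValueError("cycles and n_images must be positive")
        if self.frequency <= 0 or self.bandwidth_in <= 0 or self.bandwidth_out <= 0:
            raise ValueError("frequency and bandwidths must be positive")
        if self.bytes_in < 0 or self.bytes_out < 0:
            raise ValueError("byte counts must be nonnegative")
        if not (1 <= self.kernels_k <= MAX_KERNELS):
            raise ValueError(f"kernels_k must lie in [1, {MAX_KERNELS}], got {self.kernels_k}")

    @classmethod
    def for_image(
        cls,
        rows: int,
        cols: int,
        frequency: float,
        bandwidth_in: float,
        bandwidth_out: float,
        n_images: int = 1,
        kernels_k: int = 1,
        bytes_per_pixel: int = BYTES_PER_PIXEL,
    ) -> "PerfScenario":
        """Scenario for n images of rows x cols streamed as 32-bit words."""
        px = rows * cols
        return cls(
            cycles=px,
            frequency=frequency,
            bytes_in=px * bytes_per_pixel,
            bytes_out=px * bytes_per_pixel,
            bandwidth_in=bandwidth_in,
            bandwidth_out=bandwidth_out,
            n_images=n_images,
            kernels_k=kernels_k,
        )

    def with_k(self, k: int) -> "PerfScenario":
        return replace(self, kernels_k=k)

    def processing_term(self) -> float:
        waves = math.ceil(self.n_images / self.kernels_k)
        return processing_time(waves * self.cycles, self.frequency)

    def pcie_term(self) -> float:
        return pcie_time(
            self.n_images * self.bytes_in,
            self.bandwidth_in,
            self.n_images * self.bytes_out,
            self.bandwidth_out,
        )


def total_time(scenario: PerfScenario) -> float:
    """Modeled wall time: max(processing term, PCIe term), i.e. full overlap."""
    return max(scenario.processing_term(), scenario.pcie_term())


def saturation_point(scenario: PerfScenario) -> int | None:
    """Smallest k in [1, 8] at which transfer time bounds the run.

    Returns the first k with processing term <= PCIe term, or None when the
    design is still compute-bound at k = 8 ("not reached within 8").
    """
    pcie = scenario.pcie_term()
    for k in range(1, MAX_KERNELS + 1):
        if scenario.with_k(k).processing_term() <= pcie:
            return k
    return None


def sweep_kernels(scenario: PerfScenario) -> list[dict]:
    """total_time and speedup-vs-k=1 for k = 1..8."""
    base = total_time(scenario.with_k(1))
    rows = []
    for k in range(1, MAX_KERNELS + 1):
        t = total_time(scenario.with_k(k))
        rows.append(
            {
                "k": k,
                "processing_s": scenario.with_k(k).processing_term(),
                "pcie_s": scenario.pcie_term(),
                "total_s": t,
                "speedup_vs_k1": base / t,
            }
        )
    return rows


def report_table(scenario: PerfScenario, sep: str = "\t") -> str:
    """Plain-text table of the k = 1..8 sweep (header + one line per k)."""
    rows = sweep_kernels(scenario)
    header = sep.join(["k", "processing_s", "pcie_s", "total_s", "speedup_vs_k1"])
    lines = [header]
    for r in rows:
        lines.append(
            sep.join(
                [
                    str(r["k"]),
                    f"{r['processing_s']:.9g}",
                    f"{r['pcie_s']:.9g}",
                    f"{r['total_s']:.9g}",
                    f"{r['speedup_vs_k1']:.6g}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
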