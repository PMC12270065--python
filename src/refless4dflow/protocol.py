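"""Scan-time and temporal-resolution accounting for segmented phase-contrast protocols.

In a retrospectively gated, k-space-segmented cine acquisition every velocity
encoding of a timeframe is interleaved within the cardiac cycle, so the
effective temporal footprint of one timeframe is

    dt = segmentation_factor * n_encodings * TR

while the number of cardiac cycles needed (hence scan time) scales with
k-space lines / segmentation_factor.  Dropping the reference encoding
(4 -> 3 encodings) therefore buys either temporal resolution or, by raising
the segmentation factor, scan time.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ProtocolParams:
    """Parameters of one segmented cine phase-contrast protocol.

    Parameters
    ----------
    tr_ms : repetition time in milliseconds.
    segmentation_factor : k-space lines acquired per encoding per timeframe
        per cardiac cycle.
    n_encodings : velocity encodings per timeframe (4 for the conventional
        non-symmetric 4-point scheme, 3 for referenceless).
    n_kspace_lines : optional total phase-encode lines, for absolute times.
    rr_s : optional RR interval in seconds.
    """

    tr_ms: float
    segmentation_factor: int
    n_encodings: int
    n_kspace_lines: int | None = None
    rr_s: float | None = None

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.segmentation_factor <= 0:
            raise ValueError("segmentation_factor must be positive")
        if self.n_encodings <= 0:
            raise ValueError("n_encodings must be positive")


def temporal_resolution_ms(p: ProtocolParams) -> float:
    """Effective temporal resolution (ms) of one reconstructed timeframe."""
    return p.segmentation_factor * p.n_encodings * p.tr_ms


def scan_time_reduction_pct(full: ProtocolParams, refless: ProtocolParams) -> float:
    """Percent scan-time reduction moving from ``full`` to ``refless``.

    Scan time is proportional to the number of cardiac cycles,
    lines / segmentation_factor, so the reduction depends only on the two
    segmentation factors.
    """
    if full.segmentation_factor <= 0 or refless.segmentation_factor <= 0:
        raise ValueError("segmentation factors must be positive")
    return 100.0 * (1.0 - full.segmentation_factor / refless.segmentation_factor)


def data_reduction_pct(n_enc_full: int, n_enc_refless: int) -> float:
    """Percent reduction in acquired data from dropping encodings."""
    if n_enc_full <= 0 or n_enc_refless <= 0:
        raise ValueError("encoding counts must be positive")
    return 100.0 * (1.0 - n_enc_refless / n_enc_full)


def scan_time_s(p: ProtocolParams) -> float:
    """Absolute scan time in seconds; needs n_kspace_lines and rr_s."""
    if p.n_kspace_lines is None or p.rr_s is None:
        raise ValueError("n_kspace_lines and rr_s are required for absolute scan time")
    import math

    cycles = math.ceil(p.n_kspace_lines / p.segmentation_factor)
    return cycles * p.rr_s
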