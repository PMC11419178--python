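"""Diffusion wavelet filter banks built from powers of the diffusion operator.

Given a nondecreasing integer scale sequence ``s_0 <= s_1 <= ... <= s_J``
with ``s_0 = 0`` and ``s_1 = 1``, the filter bank consists of the band-pass
wavelets ``Psi_i = P^{s_i} - P^{s_{i+1}}`` for ``i = 0, ..., J-1`` and the
low-pass scaling filter ``Phi_J = P^{s_J}``.  Because ``s_0 = 0`` the bank
telescopes: the filter outputs sum back to the input signal exactly, so the
transform is a lossless multiscale decomposition.  Since the spectrum of the
diffusion operator lies in ``[0, 1]``, each wavelet response
``lambda^{s_i} - lambda^{s_{i+1}}`` lies in ``[0, 1]`` as well: the filters
act as band-pass windows over the diffusion spectrum.

The transform never realizes ``P`` densely.  It runs ``s_J`` diffusion steps
on the signal matrix, snapshotting at each requested scale, which costs one
sparse matvec per unit power per channel — linear in ``s_J``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypergraph import DiffusionOperator

__all__ = [
    "ScaleSequence",
    "WaveletCoefficients",
    "make_scales",
    "wavelet_transform",
    "flatten_coefficients",
    "coefficients_to_table",
]


@dataclass(frozen=True)
class ScaleSequence:
    """Validated diffusion-scale sequence ``(s_0, ..., s_J)``.

    Requires ``s_0 = 0``, ``s_1 = 1`` and nondecreasing entries.  Ties are
    allowed and produce an identically-zero wavelet filter.
    """

    scales: tuple[int, ...]

    def __post_init__(self) -> None:
        scales = tuple(int(s) for s in self.scales)
        object.__setattr__(self, "scales", scales)
        if len(scales) < 2:
            raise ValueError("need at least two scales (J >= 1)")
        if scales[0] != 0:
            raise ValueError(f"s_0 must be 0, got {scales[0]}")
        if scales[1] != 1:
            raise ValueError(f"s_1 must be 1, got {scales[1]}")
        if any(b < a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be nondecreasing")

    @property
    def J(self) -> int:
        """Number of wavelet (band-pass) filters."""
        return len(self.scales) - 1

    @property
    def max_scale(self) -> int:
        return self.scales[-1]

    def __iter__(self):
        return iter(self.scales)


def make_scales(J: int, scheme: str = "dyadic", custom=None) -> ScaleSequence:
    """Construct a scale sequence.

    ``dyadic`` gives ``(0, 1, 2, 4, ..., 2^{J-1})``, ``linear`` gives
    ``(0, 1, ..., J)``; ``custom`` validates a user-provided sequence.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    if scheme == "dyadic":
        return ScaleSequence((0,) + tuple(2**i for i in range(J)))
    if scheme == "linear":
        return ScaleSequence(tuple(range(J + 1)))
    if scheme == "custom":
        if custom is None:
            raise ValueError("custom scheme requires a sequence")
        seq = ScaleSequence(tuple(custom))
        if seq.J != J:
            raise ValueError(f"custom sequence has J={seq.J}, expected {J}")
        return seq
    raise ValueError(f"unknown scale scheme {scheme!r}")


@dataclass
class WaveletCoefficients:
    """Outputs of a wavelet filter bank applied to a signal matrix.

    ``psi[i]`` holds ``Psi_i x`` for ``i = 0..J-1`` and ``phi`` holds
    ``Phi_J x``; each has the shape of the input.  The telescoping identity
    ``sum_i psi[i] + phi == x`` holds to numerical precision.
    """

    psi: list[np.ndarray]
    phi: np.ndarray
    scales: ScaleSequence
    signal_shape: tuple[int, int]

    @property
    def J(self) -> int:
        return len(self.psi)

    def reconstruct(self) -> np.ndarray:
        """Sum of all filter outputs; equals the input signal."""
        return sum(self.psi) + self.phi


def wavelet_transform(
    op: DiffusionOperator, signals: np.ndarray, scales: ScaleSequence
) -> WaveletCoefficients:
    """Apply the diffusion wavelet bank to an ``n x c`` signal matrix.

    Powers ``P^s x`` are computed incrementally (one diffusion step at a
    time, reusing the previous power), never from scratch per scale and
    never through a dense operator.
    """
    x = np.asarray(signals, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.ndim != 2 or x.shape[0] != op.n:
        raise ValueError(f"signals must be {op.n} x c, got shape {x.shape}")

    snapshots: list[np.ndarray] = []
    wanted = list(scales.scales)
    current = x.copy()
    power = 0
    for s in wanted:
        while power < s:
            current = op.step(current)
            power += 1
        snapshots.append(current)
    # Consecutive equal scales share the same snapshot object; the
    # difference below is then exactly zero.
    psi = [snapshots[i] - snapshots[i + 1] for i in range(len(wanted) - 1)]
    phi = snapshots[-1].copy()
    if squeeze:
        psi = [p.ravel() for p in psi]
        phi = phi.ravel()
    return WaveletCoefficients(
        psi=psi, phi=phi, scales=scales, signal_shape=(x.shape[0], x.shape[1])
    )


def flatten_coefficients(
    wc: WaveletCoefficients, mode: str = "concatenate"
) -> np.ndarray:
    """Per-vertex concatenation of all filter outputs.

    Order is ``Psi_0, ..., Psi_{J-1}, Phi_J``; output is ``n x (c * (J+1))``.
    ``concatenate_abs`` takes entrywise magnitudes first.
    """
    if mode not in ("concatenate", "concatenate_abs"):
        raise ValueError(f"unknown flatten mode {mode!r}")
    blocks = [np.atleast_2d(p.T).T for p in wc.psi] + [np.atleast_2d(wc.phi.T).T]
    out = np.hstack(blocks)
    if mode == "concatenate_abs":
        out = np.abs(out)
    return out


def coefficients_to_table(
    wc: WaveletCoefficients, vertex_ids=None, channel_ids=None
) -> pd.DataFrame:
    """Long-format export: one row per (vertex, filter, channel) value.

    Filter labels are ``psi_0 .. psi_{J-1}`` and ``phi``.
    """
    n, c = wc.signal_shape
    if vertex_ids is None:
        vertex_ids = np.arange(n)
    if channel_ids is None:
        channel_ids = np.arange(c)
    frames = []
    labels = [f"psi_{i}" for i in range(wc.J)] + ["phi"]
    mats = list(wc.psi) + [wc.phi]
    for label, mat in zip(labels, mats):
        m2 = mat.reshape(n, c)
        df = pd.DataFrame(m2, columns=channel_ids)
        df.insert(0, "vertex_id", vertex_ids)
        long = df.melt(id_vars="vertex_id", var_name="channel", value_name="value")
        long.insert(1, "filter", label)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)
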