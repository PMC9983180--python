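"""Receptor-noise-limited contrasts in JNDs, plus luminance and hue indices.

Perceptual distances follow the receptor-noise-limited (RNL) model with
log-linear receptor signals: the signal difference in cone *i* between two
stimuli *a*, *b* is ``df_i = ln(q_i^a / q_i^b)`` and the chromatic distance
is the noise-weighted opponent combination of the ``df_i``, in units of
just-noticeable differences (JNDs).  The achromatic distance uses the
luminance channel alone, ``|ln(L_a / L_b)| / nu`` with the luminance-channel
Weber fraction ``nu``.

Distances below :data:`JND_DETECTION` (1 JND) are not discriminable;
:data:`JND_CONSERVATIVE` (3 JND) is a commonly used conservative detection
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observers import Observer, weber_fractions

__all__ = [
    "ConeCatchVector",
    "JND_DETECTION",
    "JND_CONSERVATIVE",
    "luminance_index",
    "hue_index",
    "achromatic_jnd",
    "chromatic_jnd",
    "chromatic_jnd_arrays",
]

#: Detection threshold: contrasts below one JND are not distinguishable.
JND_DETECTION = 1.0
#: Conservative detection threshold used for suprathreshold judgements.
JND_CONSERVATIVE = 3.0


@dataclass(frozen=True)
class ConeCatchVector:
    """Per-receptor quantum catches of one stimulus for one observer."""

    observer: Observer
    q: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.q) != self.observer.n_cones:
            raise ValueError(
                f"{len(self.q)} catches for observer with {self.observer.n_cones} cones"
            )
        object.__setattr__(self, "q", tuple(float(v) for v in self.q))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.q, dtype=float)


def _check_pair(a: ConeCatchVector, b: ConeCatchVector) -> None:
    if a.observer is not b.observer and a.observer != b.observer:
        raise ValueError("cone-catch vectors belong to different observers")


def luminance_index(catch: ConeCatchVector) -> float:
    """Luminance channel: arithmetic mean catch of the designated cones.

    For the built-in trichromats these are the two longer-wavelength
    (double) cones; for the dichromatic scorpionfish the channel degenerates
    to the single 530 nm double cone.
    """
    q = catch.as_array()
    return float(q[list(catch.observer.luminance_cones)].mean())


def hue_index(catch: ConeCatchVector) -> float:
    """Opponent hue ratio ((lw + mw) - sw) / (lw + mw + sw), in [-1, 1].

    Higher values indicate reflectance shifted toward longer wavelengths.
    Defined for trichromats only.
    """
    if catch.observer.n_cones != 3:
        raise ValueError("hue index requires a trichromatic observer")
    sw, mw, lw = catch.q
    total = sw + mw + lw
    if total <= 0:
        raise ValueError("hue undefined for zero total catch")
    return ((lw + mw) - sw) / total


def achromatic_jnd(a: ConeCatchVector, b: ConeCatchVector) -> float:
    """Achromatic (luminance) contrast |ln(L_a / L_b)| / nu in JNDs.

    The luminance-channel Weber fraction is the observer's reference value
    ``nu`` directly (not abundance-scaled).
    """
    _check_pair(a, b)
    la, lb = luminance_index(a), luminance_index(b)
    if la <= 0 or lb <= 0:
        raise ValueError("achromatic contrast undefined for non-positive luminance")
    return abs(np.log(la / lb)) / a.observer.weber_ref


def chromatic_jnd(a: ConeCatchVector, b: ConeCatchVector) -> float:
    """Chromatic RNL contrast between two stimuli in JNDs.

    Closed forms for di- and trichromats with log-linear signals
    df_i = ln(q_i^a / q_i^b):

    - dichromat:  |df_1 - df_2| / sqrt(w_1^2 + w_2^2)
    - trichromat: sqrt( (w1^2 (df2-df3)^2 + w2^2 (df1-df3)^2 + w3^2 (df1-df2)^2)
                        / ((w1 w2)^2 + (w1 w3)^2 + (w2 w3)^2) )
    """
    _check_pair(a, b)
    qa, qb = a.as_array(), b.as_array()
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("chromatic contrast requires strictly positive catches")
    df = np.log(qa / qb)
    omega = weber_fractions(a.observer)
    return float(_chromatic_jnd_from_df(df, omega))


def _chromatic_jnd_from_df(df: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Vectorized over leading axes; last axis is the cone axis."""
    n = df.shape[-1]
    if n == 2:
        w1, w2 = omega
        return np.abs(df[..., 0] - df[..., 1]) / np.hypot(w1, w2)
    if n == 3:
        w1, w2, w3 = omega
        num = (
            w1**2 * (df[..., 1] - df[..., 2]) ** 2
            + w2**2 * (df[..., 0] - df[..., 2]) ** 2
            + w3**2 * (df[..., 0] - df[..., 1]) ** 2
        )
        den = (w1 * w2) ** 2 + (w1 * w3) ** 2 + (w2 * w3) ** 2
        return np.sqrt(num / den)
    raise ValueError(f"closed forms implemented for 2 or 3 cones, got {n}")


def chromatic_jnd_arrays(qa: np.ndarray, qb: np.ndarray, observer: Observer) -> np.ndarray:
    """Chromatic JND between two stacks of catch vectors (last axis = cones).

    Used by the image pipeline to evaluate the RNL distance per pixel.
    """
    qa = np.asarray(qa, dtype=float)
    qb = np.asarray(qb, dtype=float)
    if qa.shape[-1] != observer.n_cones or qb.shape[-1] != observer.n_cones:
        raise ValueError("last axis must match the observer's cone count")
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("chromatic contrast requires strictly positive catches")
    df = np.log(qa / qb)
    return _chromatic_jnd_from_df(df, weber_fractions(observer))
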