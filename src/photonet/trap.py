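"""Biophysical promoter-occupancy scoring of TF binding (the TRAP model).

A PWM is converted into a mismatch-energy matrix: at each motif position the
energy of the preferred (consensus) base is zero and every other base pays
``ln(w_max / w_b) / lambda``, where ``w`` are pseudocount-regularised PWM
weights and ``lambda`` scales mismatch energies in thermal units (beta = 1).
A site of width W then binds with the Fermi-function probability

    p = R0 * exp(-E) / (1 + R0 * exp(-E)),

where ``R0 = K(S0) * [TF]`` collects the equilibrium constant of the
consensus site and the TF concentration, and E is the summed mismatch energy
of the site.  The promoter affinity score N is the expected occupancy: the
sum of p over every window on both strands.  N lies in [0, 2*(L-W+1)].

Because neither the TF concentration nor K(S0) is observable here, R0
defaults to the published TRAP width calibration ``ln R0 = 0.584*W - 5.66``
and can be overridden per TF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PWM, PromoterRecord

__all__ = [
    "EnergyModel",
    "AffinityMatrix",
    "default_r0",
    "build_energy_model",
    "site_probability",
    "affinity_score",
    "affinity_matrix",
    "top_n_overlap",
    "lambda_sweep",
    "DEFAULT_LAMBDA",
    "UNIFORM_BACKGROUND",
]

DEFAULT_LAMBDA = 0.7
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}
# reverse complement in code space; N stays N
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def default_r0(width: int) -> float:
    """Published TRAP calibration of R0 against motif width."""
    return math.exp(0.584 * width - 5.66)


@dataclass(frozen=True)
class EnergyModel:
    """Lambda-scaled mismatch-energy matrix for one TF.

    ``energy`` is W x 4 (A,C,G,T order) with the consensus base at zero in
    every row; ``background`` is the base composition used to regularise the
    PWM and to score N bases (a window containing N is charged the
    background-expected energy at that position).
    """

    tf_id: str
    lam: float
    energy: np.ndarray
    r0: float
    consensus: str
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND

    @property
    def width(self) -> int:
        return self.energy.shape[0]

    @property
    def energy_with_n(self) -> np.ndarray:
        """W x 5 energy table; column 4 scores an N base."""
        bg = np.asarray(self.background)
        expected = self.energy @ bg
        return np.hstack([self.energy, expected[:, None]])


@dataclass(frozen=True)
class AffinityMatrix:
    """TF x gene table of expected-occupancy scores N."""

    tf_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    scores: np.ndarray  # len(tf_ids) x len(gene_ids); NaN marks unscorable cells

    def row(self, tf_id: str) -> pd.Series:
        """Per-gene scores of one TF."""
        i = self.tf_ids.index(tf_id)
        return pd.Series(self.scores[i], index=list(self.gene_ids), name=tf_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.tf_ids), columns=list(self.gene_ids))


def build_energy_model(
    pwm: PWM,
    lam: float = DEFAULT_LAMBDA,
    pseudocount: float = 1.0,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    r0: float | None = None,
) -> EnergyModel:
    """Convert a PWM into a mismatch-energy model.

    Weights are regularised as ``w = count + pseudocount * background_b``;
    the per-position consensus is the argmax base (ties broken alphabetically
    A < C < G < T) and carries zero energy.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    w = pwm.matrix + pseudocount * bg[None, :]
    if np.any(w <= 0):
        raise ValueError(
            f"PWM {pwm.tf_id!r}: zero weight with pseudocount {pseudocount}; "
            "energies undefined"
        )
    w = w / w.sum(axis=1, keepdims=True)
    imax = np.argmax(w, axis=1)  # argmax takes the first maximum: A<C<G<T
    wmax = w[np.arange(w.shape[0]), imax]
    energy = np.log(wmax[:, None] / w) / lam
    consensus = "".join(_BASES[i] for i in imax)
    return EnergyModel(
        tf_id=pwm.tf_id,
        lam=lam,
        energy=energy,
        r0=default_r0(pwm.width) if r0 is None else r0,
        consensus=consensus,
        background=tuple(bg),
    )


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in sequence") from None


def site_probability(model: EnergyModel, site: str) -> float:
    """Binding probability of a single width-W site."""
    site = site.upper()
    if len(site) != model.width:
        raise ValueError(f"site length {len(site)} != motif width {model.width}")
    codes = _encode(site)
    e5 = model.energy_with_n
    E = float(e5[np.arange(model.width), codes].sum())
    z = model.r0 * math.exp(-E)
    return z / (1.0 + z)


def _window_energies(codes: np.ndarray, e5: np.ndarray) -> np.ndarray:
    """Summed energies of all length-W windows of an encoded sequence."""
    W = e5.shape[0]
    n_win = codes.size - W + 1
    E = np.zeros(n_win)
    for i in range(W):
        E += e5[i, codes[i : i + n_win]]
    return E


def affinity_score(model: EnergyModel, promoter: PromoterRecord | str) -> float:
    """Expected occupancy N: Fermi-function binding probabilities summed over
    all L-W+1 windows of the promoter and of its reverse complement."""
    seq = promoter.sequence if isinstance(promoter, PromoterRecord) else promoter.upper()
    if len(seq) < model.width:
        raise ValueError(
            f"promoter length {len(seq)} shorter than motif width {model.width}"
        )
    codes = _encode(seq)
    rc = _RC_CODE[codes][::-1]
    e5 = model.energy_with_n
    total = 0.0
    for strand_codes in (codes, rc):
        E = _window_energies(strand_codes, e5)
        z = model.r0 * np.exp(-E)
        total += float((z / (1.0 + z)).sum())
    return total


def affinity_matrix(
    pwms: Sequence[PWM],
    promoters: Sequence[PromoterRecord],
    lam: float = DEFAULT_LAMBDA,
    pseudocount: float = 1.0,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    r0_override: Mapping[str, float] | None = None,
) -> AffinityMatrix:
    """Score every TF against every promoter.

    A promoter shorter than some motif yields a NaN cell and a warning
    rather than an error, so one short extract does not abort a genome scan.
    """
    if not pwms or not promoters:
        raise ValueError("affinity_matrix requires at least one PWM and one promoter")
    r0_override = r0_override or {}
    scores = np.full((len(pwms), len(promoters)), np.nan)
    for i, pwm in enumerate(pwms):
        model = build_energy_model(
            pwm, lam=lam, pseudocount=pseudocount, background=background,
            r0=r0_override.get(pwm.tf_id),
        )
        for j, prom in enumerate(promoters):
            if len(prom) < model.width:
                warnings.warn(
                    f"promoter {prom.gene_id!r} shorter than motif {pwm.tf_id!r}; "
                    "cell left missing"
                )
                continue
            scores[i, j] = affinity_score(model, prom)
    return AffinityMatrix(
        tf_ids=tuple(p.tf_id for p in pwms),
        gene_ids=tuple(p.gene_id for p in promoters),
        scores=scores,
    )


def _top_n(scores: pd.Series, n: int) -> set[str]:
    # descending score, ties broken by ascending gene id
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return set(order[:n])


def top_n_overlap(scores_a: pd.Series, scores_b: pd.Series, n: int) -> float:
    """Fraction of shared genes among the top-n of two per-gene score vectors."""
    if n <= 0:
        raise ValueError("n must be positive")
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("score vectors must cover the same gene universe")
    if n > len(scores_a):
        raise ValueError(f"n={n} exceeds number of genes {len(scores_a)}")
    return len(_top_n(scores_a, n) & _top_n(scores_b, n)) / n


def lambda_sweep(
    pwm: PWM,
    promoters: Sequence[PromoterRecord],
    lambdas: Sequence[float] = (0.5, 0.6, 0.65, 0.7, 0.75, 0.8, 0.9),
    n: int = 1000,
    reference_lambda: float = DEFAULT_LAMBDA,
    pseudocount: float = 1.0,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    r0: float | None = None,
) -> pd.DataFrame:
    """Sensitivity of the top-n target ranking to the energy scale lambda.

    Each lambda's per-gene scores are compared against the reference
    (lambda = 0.7 by default) via top-n overlap; the reference row is 1.0 by
    construction.
    """
    n = min(n, len(promoters))

    def scores_at(lam: float) -> pd.Series:
        model = build_energy_model(pwm, lam=lam, pseudocount=pseudocount,
                                   background=background, r0=r0)
        return pd.Series(
            {p.gene_id: affinity_score(model, p) for p in promoters}
        )

    ref = scores_at(reference_lambda)
    rows = []
    for lam in lambdas:
        s = ref if lam == reference_lambda else scores_at(lam)
        rows.append({"lambda": lam, "top_n_overlap": top_n_overlap(s, ref, n)})
    return pd.DataFrame(rows)
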