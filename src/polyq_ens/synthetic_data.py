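"""Synthetic inputs with the statistical structure the analysis assumes.

Generates everything the pipeline consumes without molecular dynamics or a
spectrometer: a 62-residue ARR-polyQ-PRR fragment, conformer pools whose
per-residue helix frequency follows a prescribed propensity profile,
ensemble-averaged "experimental" shifts from a known ground-truth weight
vector plus Gaussian noise, and HDX intensity decay series with
slow-exchanging ARR/polyQ amides.

The stand-in sequence follows the ataxin-7 N-terminal block layout (NT,
ARR1, ARR2, Arg29, polyQ at 30-39 in the normal-length frame, PRR at
40-62); it is a synthetic construction, not the deposited wild-type
sequence. Expanded variants insert extra glutamines after residue 39,
labelled fractionally (39 + k/100) so that the normal-frame numbering of
all other residues is preserved.

Randomness: one seed per scenario, split into fixed per-operation streams
(pool sampling, shift noise, HDX noise, ground-truth weights), so adding an
operation never perturbs another operation's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conformer_model import Conformer, build_chain
from .forward_shift_model import pool_matrix, supported_observables
from .hdx_classification import HDXSeries
from .refdata import NUCLEI
from .shift_data import RandomCoilTable, ShiftTable

__all__ = [
    "Scenario",
    "PRESETS",
    "make_scenario",
    "sample_pool",
    "synth_experimental_shifts",
    "synth_hdx",
]

# fixed sub-stream labels for the per-scenario RNG
_STREAM_POOL = 1
_STREAM_SHIFTS = 2
_STREAM_HDX = 3
_STREAM_WEIGHTS = 4

# sequence blocks (10Q frame); residue numbers in comments
_NT = "MSERAADGSGR"  # 1-11
_ARR1 = "AAASAAGA"  # 12-19 (Ala19)
_LINKER = "GSA"  # 20-22
_ARR2 = "AAAAAA"  # 23-28 (Ala24-Ala28 interior)
_ARG = "R"  # 29
_PRR = "PPPQPPPRPPPSPPPLPPPQPPP"  # 40-62, proline-rich

ARR1_REGION = (12, 19)
ARR2_REGION = (23, 28)
POLYQ_START = 30
POLYQ_END_10Q = 39
PRR_REGION = (40, 62)

PRESETS = ("normal_10Q", "expanded_22Q", "expanded_33Q", "helix_broken")
_PRESET_POLYQ = {
    "normal_10Q": 10,
    "expanded_22Q": 22,
    "expanded_33Q": 33,
    "helix_broken": 33,
}

# propensity levels
_P_NT = 0.05
_P_ARR1 = 0.30
_P_ARR2 = 0.70
_P_ARR2_BROKEN = 0.05
_P_POLYQ_BASE = 0.15
_P_POLYQ_BOOST = 0.45  # added at the ARR-adjacent end of an expanded tract
_POLYQ_DECAY = 5.0  # residues; e-folding of the boost along the tract
_P_PRR = 0.02

# helix-run sampling
_STOP_PROB = 0.35  # per-step stop probability after the minimum run
_MIN_RUN = 4
_MEAN_RUN = _MIN_RUN + (1.0 - _STOP_PROB) / _STOP_PROB


@dataclass
class Scenario:
    """Ground truth for one synthetic study condition."""

    preset: str
    sequence: str
    labels: np.ndarray  # 10Q-frame residue labels (fractional = insertion)
    helix_propensity: np.ndarray  # per-residue P(helix), in [0, 1]
    polyq_len: int
    pool_size: int = 100
    noise_sd: float = 0.05  # ppm, Gaussian noise on synthetic shifts
    seed: int = 0
    ground_truth_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        self.helix_propensity = np.asarray(self.helix_propensity, dtype=float)
        n = len(self.sequence)
        if self.labels.shape != (n,) or self.helix_propensity.shape != (n,):
            raise ValueError("labels/propensity must have one entry per residue")
        if ((self.helix_propensity < 0) | (self.helix_propensity > 1)).any():
            raise ValueError("propensities must lie in [0, 1]")
        if self.ground_truth_weights is not None:
            w = np.asarray(self.ground_truth_weights, dtype=float)
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("ground-truth weights must lie on the simplex")
            self.ground_truth_weights = w

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def truth_weights(self, k: int | None = None) -> np.ndarray:
        """Ground-truth simplex weights (Dirichlet(1) draw if not fixed)."""
        if self.ground_truth_weights is not None:
            return self.ground_truth_weights
        k = self.pool_size if k is None else k
        return self.rng(_STREAM_WEIGHTS).dirichlet(np.ones(k))

    def region_mask(self, region: tuple[float, float]) -> np.ndarray:
        lo, hi = region
        return (self.labels >= lo) & (self.labels < math.floor(hi) + 1)

    @property
    def polyq_region(self) -> tuple[int, int]:
        return (POLYQ_START, POLYQ_END_10Q)


def _sequence_and_labels(polyq_len: int) -> tuple[str, np.ndarray]:
    sequence = _NT + _ARR1 + _LINKER + _ARR2 + _ARG + "Q" * polyq_len + _PRR
    labels = list(np.arange(1, POLYQ_START, dtype=float))  # 1..29
    labels += list(np.arange(POLYQ_START, POLYQ_END_10Q + 1, dtype=float))
    labels += [POLYQ_END_10Q + k / 100.0 for k in range(1, polyq_len - 10 + 1)]
    labels += list(np.arange(PRR_REGION[0], PRR_REGION[1] + 1, dtype=float))
    return sequence, np.array(labels)


def make_scenario(
    preset: str,
    seed: int,
    pool_size: int = 100,
    noise_sd: float = 0.05,
    ground_truth_weights: np.ndarray | None = None,
) -> Scenario:
    """Build the deterministic ground truth for a named study condition.

    ``normal_10Q``: high helix propensity over ARR2, low over the 10Q tract.
    ``expanded_22Q``/``expanded_33Q``: polyQ propensity raised next to the
    ARR and decaying along the tract. ``helix_broken``: the ARR2 helix is
    disrupted (as by A26G/A26P/del25-27) and the tract loses its boost.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    polyq_len = _PRESET_POLYQ[preset]
    sequence, labels = _sequence_and_labels(polyq_len)

    p = np.full(len(sequence), _P_NT)
    p[(labels >= ARR1_REGION[0]) & (labels <= ARR1_REGION[1])] = _P_ARR1
    arr2_level = _P_ARR2_BROKEN if preset == "helix_broken" else _P_ARR2
    # ARR2 helix runs through Arg29 up to the tract
    p[(labels >= ARR2_REGION[0]) & (labels <= ARR2_REGION[1] + 1)] = arr2_level
    in_polyq = (labels >= POLYQ_START) & (labels < PRR_REGION[0])
    tract = np.flatnonzero(in_polyq)
    boosted = preset in ("expanded_22Q", "expanded_33Q")
    for j, idx in enumerate(tract):
        if boosted:
            p[idx] = _P_POLYQ_BASE + _P_POLYQ_BOOST * math.exp(-j / _POLYQ_DECAY)
        else:
            p[idx] = _P_POLYQ_BASE
    p[labels >= PRR_REGION[0]] = _P_PRR

    return Scenario(
        preset=preset,
        sequence=sequence,
        labels=labels,
        helix_propensity=p,
        polyq_len=polyq_len,
        pool_size=pool_size,
        noise_sd=noise_sd,
        seed=seed,
        ground_truth_weights=ground_truth_weights,
    )


# --------------------------------------------------------------------------
# conformer pool sampling
# --------------------------------------------------------------------------

def _nucleation_prob(p_bar: float) -> float:
    """Per-coil-residue helix nucleation probability.

    Chosen so the renewal process (mean run length L, geometric gaps of mean
    1/q) covers each residue with probability ~= its propensity:
    coverage = L / (L + 1/q)  =>  q = p / (L * (1 - p)).
    """
    if p_bar >= 1.0:
        return 1.0
    return min(1.0, p_bar / (_MEAN_RUN * (1.0 - p_bar)))


def _helix_mask(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(p)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        start, end = i, i + _MIN_RUN
        if end > n:  # anchor a chain-end run backwards to keep length 4
            start, end = max(0, n - _MIN_RUN), n
        p_bar = float(p[start:end].mean())
        if rng.random() < _nucleation_prob(p_bar):
            mask[start:end] = True
            j = end
            ref = max(p_bar, 1e-9)
            while j < n and rng.random() < (1.0 - _STOP_PROB) * min(
                1.0, p[j] / ref
            ):
                mask[j] = True
                j += 1
            i = max(j, i + 1)
        else:
            i += 1
    return mask


def _draw_dihedrals(
    mask: np.ndarray, rng: np.random.Generator, strand_prob: float = 0.15
) -> np.ndarray:
    """(phi, psi) per residue: helix basin under the mask, PPII/strand coil."""
    n = len(mask)
    dih = np.zeros((n, 2))
    for i in range(n):
        if mask[i]:
            phi = np.clip(rng.normal(-57.0, 6.0), -95.0, -35.0)
            psi = np.clip(rng.normal(-47.0, 6.0), -75.0, -5.0)
        elif rng.random() < strand_prob:
            phi = np.clip(rng.normal(-120.0, 10.0), -170.0, -95.0)
            psi = np.clip(rng.normal(135.0, 10.0), 95.0, 175.0)
        else:  # polyproline-II-like coil; outside both basins
            phi = np.clip(rng.normal(-75.0, 8.0), -89.0, -40.0)
            psi = np.clip(rng.normal(145.0, 8.0), 120.0, 175.0)
        dih[i] = (phi, psi)
    return dih


def sample_pool(scenario: Scenario, k: int | None = None) -> list[Conformer]:
    """Draw a conformer pool whose helix frequency follows the propensity.

    Helical segments nucleate per residue and extend as runs of at least 4;
    dihedrals are drawn inside the corresponding basin with jitter and
    coordinates are built with ideal geometry.
    """
    k = scenario.pool_size if k is None else k
    if k < 1:
        raise ValueError("pool size must be >= 1")
    rng = scenario.rng(_STREAM_POOL)
    pool = []
    for m in range(k):
        mask = _helix_mask(scenario.helix_propensity, rng)
        dih = _draw_dihedrals(mask, rng)
        pool.append(
            build_chain(scenario.sequence, dih, source=f"{scenario.preset}:{m}")
        )
    return pool


def pool_helix_frequency(pool: list[Conformer]) -> np.ndarray:
    """Empirical per-residue helix frequency over a pool."""
    counts = np.zeros(len(pool[0]))
    for conf in pool:
        counts += np.frombuffer(conf.ss.encode(), dtype="S1") == b"H"
    return counts / len(pool)


# --------------------------------------------------------------------------
# synthetic experimental observables
# --------------------------------------------------------------------------

def synth_experimental_shifts(
    pool: list[Conformer],
    weights: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
    rc: RandomCoilTable | None = None,
    nuclei: tuple[str, ...] = NUCLEI,
    label: str = "",
) -> ShiftTable:
    """Ensemble-averaged predicted shifts under known weights plus noise.

    exp_j = sum_k w_k * predict(pool_k)_j + eps_j,  eps ~ N(0, noise_sd^2).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(pool):
        raise ValueError("one weight per pool conformer required")
    if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must lie on the simplex")
    rc = RandomCoilTable.default() if rc is None else rc
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng([seed, _STREAM_SHIFTS])
    )
    observables = supported_observables(pool[0].sequence, rc, nuclei)
    matrix = pool_matrix(pool, observables, rc)
    values = weights @ matrix.values
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    shifts = {
        (idx, nuc): float(v)
        for (idx, _aa, nuc), v in zip(observables, values)
    }
    return ShiftTable(sequence=pool[0].sequence, shifts=shifts, label=label)


# --------------------------------------------------------------------------
# synthetic HDX series
# --------------------------------------------------------------------------

_HDX_TIMES = (15.0, 60.0, 120.0)
_SLOW_PROPENSITY = 0.5  # residues at/above this exchange slowly
_SLOW_RATIO_RANGE = (0.55, 0.90)  # 15-min ratio of a protected amide
_FAST_RATIO_MAX = 0.04
_HDX_NOISE_SD = 0.05  # multiplicative log-normal measurement noise


def synth_hdx(scenario: Scenario, seed: int | None = None) -> HDXSeries:
    """HDX intensity decay series consistent with the helix propensities.

    Residues with helix propensity >= 0.5 keep >= ~0.5 of their control
    intensity after 15 min (slow exchangers); all others drop to <= ~0.05.
    Prolines carry no amide and get zero control intensity. Glutamines in
    the tract beyond the first are flagged unassigned, mimicking the
    ambiguity of repeated residues.
    """
    rng = scenario.rng(_STREAM_HDX) if seed is None else np.random.default_rng(
        [seed, _STREAM_HDX]
    )
    n = len(scenario.sequence)
    control = np.ones(n)
    intensities = np.zeros((len(_HDX_TIMES), n))
    assigned = np.ones(n, dtype=bool)
    in_polyq = (scenario.labels >= POLYQ_START) & (
        scenario.labels < PRR_REGION[0]
    )
    for i, aa in enumerate(scenario.sequence):
        if aa == "P":
            control[i] = 0.0
            continue
        control[i] = math.exp(rng.normal(0.0, _HDX_NOISE_SD))
        if scenario.helix_propensity[i] >= _SLOW_PROPENSITY:
            r15 = rng.uniform(*_SLOW_RATIO_RANGE)
        else:
            r15 = rng.uniform(0.0, _FAST_RATIO_MAX)
        for t_idx, t in enumerate(_HDX_TIMES):
            decayed = control[i] * r15 ** (t / _HDX_TIMES[0])
            intensities[t_idx, i] = decayed * math.exp(
                rng.normal(0.0, _HDX_NOISE_SD)
            )
        if in_polyq[i] and aa == "Q" and scenario.labels[i] > POLYQ_START:
            assigned[i] = False
    return HDXSeries(
        sequence=scenario.sequence,
        times=_HDX_TIMES,
        control=control,
        intensities=intensities,
        assigned=assigned,
        labels=scenario.labels,
        name=scenario.preset,
    )
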