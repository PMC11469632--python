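"""Base Shannon-energy segmentation: lobe validation and S1/S2 identification.

Candidate lobes from the envelope are first validated with a-priori rules:
primary heart sounds are shorter than 250 ms, and a physiological split sound
shows as two lobes less than 50 ms apart with clearly unequal energies (RMS
ratio below 40%) — in that case only the higher-energy lobe is kept.

S1 and S2 are then identified sequentially. The anchor is the lobe pair
bounding the longest inter-lobe interval: because the diastolic interval
(S2 -> next S1) is generally longer than the systolic interval (S1 -> S2),
the lobe after the longest gap is taken as an S1 and its successor as the
matching S2. From that pair the algorithm extends forward and backward,
scoring every plausible candidate pair by (a) the correlation between the
candidate's systolic-interval envelope and the reference pair's, (b) agreement
with the running cardiac-cycle estimate and (c) agreement with the running
systolic-interval estimate, and accepting the best-scoring pair at each step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .envelope import Envelope, Lobe, compute_ase, compute_nase, detect_lobes
from .io import (
    STATE_DIASTOLE,
    STATE_NOISE,
    STATE_S1,
    STATE_S2,
    STATE_SYSTOLE,
    PCGRecording,
    StateAnnotation,
)
from .preprocess import preprocess


class Label(enum.Enum):
    S1 = STATE_S1
    SYSTOLE = STATE_SYSTOLE
    S2 = STATE_S2
    DIASTOLE = STATE_DIASTOLE
    NOISE = STATE_NOISE


@dataclass(frozen=True)
class LabeledInterval:
    start_s: float
    end_s: float
    label: Label

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("interval must have start_s < end_s")

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass(frozen=True)
class Segmentation:
    """Ordered labeled intervals plus cycle/systole estimates and a success flag.

    ``success`` means at least one complete S1-S2-S1 span was identified.
    """

    intervals: tuple[LabeledInterval, ...] = ()
    success: bool = False
    cycle_length_s: float = float("nan")
    systole_s: float = float("nan")

    def labeled(self, label: Label) -> list[LabeledInterval]:
        return [iv for iv in self.intervals if iv.label is label]

    def to_annotation(self) -> StateAnnotation:
        onsets = np.array([iv.start_s for iv in self.intervals])
        offsets = np.array([iv.end_s for iv in self.intervals])
        states = np.array([iv.label.value for iv in self.intervals], dtype=np.int64)
        return StateAnnotation(onsets, offsets, states)

    @classmethod
    def from_annotation(cls, ann: StateAnnotation) -> "Segmentation":
        ivs = tuple(
            LabeledInterval(on, off, Label(st)) for on, off, st in ann.rows()
        )
        return cls(intervals=ivs, success=len(ivs) > 0)


@dataclass(frozen=True)
class SegmentationParams:
    """All tunable thresholds of the segmenter.

    max_sound_ms:
        Upper duration bound for a primary heart sound lobe (250 ms).
    max_split_ms:
        Largest gap between the two lobes of a split sound (50 ms).
    split_rms_ratio:
        Split rule fires when the weaker lobe's RMS is below this fraction of
        the stronger's (0.40).
    area_cutoff:
        Z-score cutoff for noisy-lobe rejection (2.75; used by the
        noise-robust wrapper).
    corr_weight, cycle_weight, sys_weight:
        Weights of the three pair-score terms; must sum to 1.
    min_pair_score:
        Acceptance floor for extending the S1/S2 chain.
    min_lobe_coverage:
        Success additionally requires the accepted S1/S2 sounds to account
        for at least this fraction of the validated lobes; a lobe field that
        is mostly unexplained (as produced by stationary noise) is not a
        plausible heart sound segmentation.
    cycle_window:
        Candidate next-S1 onsets are searched within
        [cycle_window[0], cycle_window[1]] x current cycle estimate.
    crop_margin_s, min_clean_duration_s:
        Noise-cropping guard band and minimum usable clean-interval length.
    """

    max_sound_ms: float = 250.0
    max_split_ms: float = 50.0
    split_rms_ratio: float = 0.40
    area_cutoff: float = 2.75
    corr_weight: float = 1.0 / 3.0
    cycle_weight: float = 1.0 / 3.0
    sys_weight: float = 1.0 / 3.0
    min_pair_score: float = 0.5
    min_lobe_coverage: float = 0.5
    cycle_window: tuple[float, float] = (0.5, 1.5)
    crop_margin_s: float = 0.050
    min_clean_duration_s: float = 2.0
    iterative_outlier_pass: bool = False

    def __post_init__(self) -> None:
        for name in ("max_sound_ms", "max_split_ms", "split_rms_ratio", "area_cutoff",
                     "min_pair_score", "crop_margin_s", "min_clean_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        wsum = self.corr_weight + self.cycle_weight + self.sys_weight
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"score weights must sum to 1, got {wsum}")

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        if "iterative_outlier_pass" in d:
            d = {**d, "iterative_outlier_pass": bool(d["iterative_outlier_pass"])}
        return cls(**d)


DEFAULT_PARAMS = SegmentationParams()


# ---------------------------------------------------------------------------
# Lobe validation (a-priori rules)
# ---------------------------------------------------------------------------

def validate_lobes(lobes: list[Lobe], params: SegmentationParams = DEFAULT_PARAMS) -> list[Lobe]:
    """Apply the duration and split rules to candidate lobes.

    Lobes lasting 250 ms or more cannot be a primary heart sound and are
    dropped. For each adjacent pair closer than 50 ms: if the weaker lobe's
    RMS is under 40% of the stronger's it is a split fragment and only the
    stronger lobe is kept; otherwise both stay candidates (the weaker one may
    be a murmur, which identification will pass over).
    """
    max_dur = params.max_sound_ms / 1e3
    kept = [lb for lb in lobes if lb.duration_s < max_dur]
    if len(kept) < 2:
        return kept
    out: list[Lobe] = [kept[0]]
    for lobe in kept[1:]:
        prev = out[-1]
        gap = lobe.start_s - prev.end_s  # gap semantics for the split rule
        if gap < params.max_split_ms / 1e3:
            lo, hi = sorted((prev.rms, lobe.rms))
            if hi > 0 and lo / hi < params.split_rms_ratio:
                if lobe.rms > prev.rms:
                    out[-1] = lobe
                continue
        out.append(lobe)
    return out


# ---------------------------------------------------------------------------
# S1/S2 identification
# ---------------------------------------------------------------------------

class SegmentationFailure(Exception):
    """Raised internally when no initial S1-S2 pair can be anchored."""


def find_initial_pair(lobes: list[Lobe]) -> tuple[int, int]:
    """Anchor the identification on the longest inter-lobe interval.

    The pair bounding the longest onset-to-onset gap is assumed to straddle a
    diastole, so the later lobe of that pair is an S1 and its immediate
    successor the matching S2. Ties break to the earliest qualifying pair.
    """
    if len(lobes) < 3:
        raise SegmentationFailure(f"need at least 3 validated lobes, have {len(lobes)}")
    onsets = np.array([lb.onset_s for lb in lobes])
    gaps = np.diff(onsets)
    # the S1 candidate needs a successor to act as S2
    order = np.argsort(-gaps[: len(lobes) - 2], kind="stable")
    i = int(order[0])
    return i + 1, i + 2


def _systole_envelope(env: Envelope, s1: Lobe, s2: Lobe) -> np.ndarray:
    """Envelope stretch covering the systolic interval of a pair (S1 through S2)."""
    return env.values[s1.start_frame : s2.end_frame + 1]


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation after resampling the shorter stretch to the longer."""
    if a.size == 0 or b.size == 0:
        return 0.0
    if a.size != b.size:
        if a.size < b.size:
            a = np.interp(np.linspace(0, a.size - 1, b.size), np.arange(a.size), a)
        else:
            b = np.interp(np.linspace(0, b.size - 1, a.size), np.arange(b.size), b)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pair_score(
    cand: tuple[Lobe, Lobe],
    ref: tuple[Lobe, Lobe],
    env: Envelope,
    cycle_s: float,
    sys_s: float,
    params: SegmentationParams = DEFAULT_PARAMS,
) -> float:
    """Score a candidate S1-S2 pair against the running reference.

    Weighted sum of the systolic-envelope correlation, the relative agreement
    of the candidate's cycle length with ``cycle_s`` and of its systolic
    interval with ``sys_s`` (both deviation terms clipped to [0, 1]).
    """
    c1, c2 = cand
    r1, r2 = ref
    corr = _correlation(_systole_envelope(env, c1, c2), _systole_envelope(env, r1, r2))
    cand_cycle = abs(c1.onset_s - r1.onset_s)
    cand_sys = c2.onset_s - c1.onset_s
    cycle_term = max(0.0, 1.0 - abs(cand_cycle - cycle_s) / cycle_s) if cycle_s > 0 else 0.0
    sys_term = max(0.0, 1.0 - abs(cand_sys - sys_s) / sys_s) if sys_s > 0 else 0.0
    return params.corr_weight * corr + params.cycle_weight * cycle_term + params.sys_weight * sys_term


def _candidate_pairs(
    lobes: list[Lobe],
    anchor_idx: int,
    direction: int,
    cycle_est: float,
    sys_est: float,
    params: SegmentationParams,
) -> list[tuple[int, int]]:
    """Enumerate plausible (S1, S2) index pairs one cycle away from the anchor S1."""
    lo, hi = params.cycle_window
    anchor_onset = lobes[anchor_idx].onset_s
    pairs: list[tuple[int, int]] = []
    for i, lb in enumerate(lobes):
        delta = direction * (lb.onset_s - anchor_onset)
        if not (lo * cycle_est <= delta <= hi * cycle_est):
            continue
        for j in range(i + 1, len(lobes)):
            sys_len = lobes[j].onset_s - lb.onset_s
            if sys_len > min(0.6 * cycle_est, 2.0 * sys_est):
                break
            pairs.append((i, j))
    return pairs


def identify_s1_s2(
    lobes: list[Lobe],
    env: Envelope,
    params: SegmentationParams = DEFAULT_PARAMS,
) -> Segmentation:
    """Greedy forward/backward S1-S2 chain extension from the initial pair.

    Running cycle-length and systolic-interval estimates are the cumulative
    means of the accepted values. Extension in a direction stops when no
    candidate pair reaches ``min_pair_score``. Lobes never chosen stay
    unlabeled. Equal best scores break to the earlier-onset pair.
    """
    try:
        i1, i2 = find_initial_pair(lobes)
    except SegmentationFailure:
        return Segmentation()

    accepted: dict[int, int] = {i1: i2}  # S1 index -> S2 index
    sys_values = [lobes[i2].onset_s - lobes[i1].onset_s]
    cycle_values: list[float] = []
    # prior cycle estimate before any accepted cycle: systole / typical fraction
    sys_est = sys_values[0]
    cycle_est = sys_est / 0.35

    for direction in (+1, -1):
        anchor_s1, anchor_s2 = i1, i2
        while True:
            cyc = float(np.mean(cycle_values)) if cycle_values else cycle_est
            sysm = float(np.mean(sys_values))
            cands = _candidate_pairs(lobes, anchor_s1, direction, cyc, sysm, params)
            cands = [(a, b) for a, b in cands if a not in accepted and b not in accepted.values()]
            if not cands:
                break
            ref = (lobes[anchor_s1], lobes[anchor_s2])
            best: tuple[int, int] | None = None
            best_score = -np.inf
            for a, b in sorted(cands, key=lambda p: lobes[p[0]].onset_s):
                score = pair_score((lobes[a], lobes[b]), ref, env, cyc, sysm, params)
                if score > best_score + 1e-12:
                    best_score = score
                    best = (a, b)
            if best is None or best_score < params.min_pair_score:
                break
            a, b = best
            accepted[a] = b
            cycle_values.append(abs(lobes[a].onset_s - lobes[anchor_s1].onset_s))
            sys_values.append(lobes[b].onset_s - lobes[a].onset_s)
            anchor_s1, anchor_s2 = a, b

    return _build_segmentation(lobes, accepted, cycle_values, sys_values, params)


def _build_segmentation(
    lobes: list[Lobe],
    accepted: dict[int, int],
    cycle_values: list[float],
    sys_values: list[float],
    params: SegmentationParams,
) -> Segmentation:
    pairs = sorted(((lobes[a], lobes[b]) for a, b in accepted.items()), key=lambda p: p[0].onset_s)
    intervals: list[LabeledInterval] = []
    for k, (s1, s2) in enumerate(pairs):
        intervals.append(LabeledInterval(s1.start_s, s1.end_s, Label.S1))
        if s2.start_s > s1.end_s:
            intervals.append(LabeledInterval(s1.end_s, s2.start_s, Label.SYSTOLE))
        intervals.append(LabeledInterval(s2.start_s, s2.end_s, Label.S2))
        if k + 1 < len(pairs):
            next_s1 = pairs[k + 1][0]
            if next_s1.start_s > s2.end_s:
                intervals.append(LabeledInterval(s2.end_s, next_s1.start_s, Label.DIASTOLE))
    # a plausible segmentation explains most of the candidate lobe field
    coverage_ok = 2 * len(pairs) >= params.min_lobe_coverage * len(lobes)
    success = len(pairs) >= 2 and coverage_ok
    return Segmentation(
        intervals=tuple(intervals),
        success=success,
        cycle_length_s=float(np.mean(cycle_values)) if cycle_values else float("nan"),
        systole_s=float(np.mean(sys_values)) if sys_values else float("nan"),
    )


# ---------------------------------------------------------------------------
# End-to-end base segmentation
# ---------------------------------------------------------------------------

def segment_preprocessed(
    rec: PCGRecording, params: SegmentationParams = DEFAULT_PARAMS
) -> Segmentation:
    """Segment an already-preprocessed (4 kHz, bandpassed, normalized) recording."""
    try:
        ase = compute_ase(rec)
    except ValueError:
        return Segmentation()
    nase = compute_nase(ase)
    lobes = detect_lobes(nase, rec)
    valid = validate_lobes(lobes, params)
    return identify_s1_s2(valid, nase, params)


def segment_base(rec: PCGRecording, params: SegmentationParams = DEFAULT_PARAMS) -> Segmentation:
    """Full base pipeline: preprocess -> ASE -> NASE -> lobes -> validate -> identify.

    Deterministic for a fixed input and params. Returns a failure-flagged
    (empty) segmentation rather than raising when the signal yields no usable
    lobe structure.
    """
    try:
        prep = preprocess(rec)
    except ValueError:
        return Segmentation()
    return segment_preprocessed(prep, params)
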