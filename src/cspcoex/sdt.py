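"""Signal-detection analysis of mating-trial behaviour.

Each behavioural response is scored against the species identity of the
stimulus animal: for male mating attempts the "correct" signal is a
conspecific female (a session with at least one attempt toward her is a
hit); for female rejection behaviour the correct signal is a heterospecific
male (rejecting his attempt is a hit, rejecting a conspecific's attempt is a
false alarm).  From the 2x2 contingency counts we compute

* ``d'`` = z(H) - z(F), the separation of signal and noise in standard
  normal units, with the log-linear correction H = (hit + 0.5) / (hit +
  miss + 1) (and likewise F) applied to every cell so that rates never
  reach 0 or 1;
* the criterion ``C = -(z(H) + z(F)) / 2`` and the response-bias likelihood
  ratio ``beta = exp((z(F)^2 - z(H)^2) / 2) = exp(d' * C)``;
* the binary-decision ROC (three points) and its AUC ``(1 + h - f) / 2``
  from the *uncorrected* rates, ties counted one-half;
* the unpaired DeLong comparison of two AUCs, with a t reference and
  Welch-Satterthwaite degrees of freedom, plus a stratified-bootstrap
  alternative used as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BEHAVIORS",
    "ContingencyCounts",
    "SDTResult",
    "ScoreSample",
    "DeLongResult",
    "SessionRecord",
    "corrected_rates",
    "sdt_statistics",
    "binary_auc",
    "BinaryROC",
    "delong_unpaired",
    "bootstrap_auc_test",
    "sessions_to_counts",
    "counts_to_scores",
    "read_counts_csv",
    "read_sessions_csv",
    "load_packaged_counts",
]

BEHAVIORS = ("male_mating_attempt", "female_rejection")


@dataclass(frozen=True)
class ContingencyCounts:
    """Hit/miss/false-alarm/correct-rejection counts for one behaviour cell."""

    hit: int
    miss: int
    false_alarm: int
    correct_rejection: int
    behavior: str = "male_mating_attempt"
    species: str = ""
    year: str = ""

    def __post_init__(self) -> None:
        for name in ("hit", "miss", "false_alarm", "correct_rejection"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.behavior not in BEHAVIORS:
            raise ValueError(
                f"behavior must be one of {BEHAVIORS}, got {self.behavior!r}"
            )

    @property
    def n_signal(self) -> int:
        return self.hit + self.miss

    @property
    def n_noise(self) -> int:
        return self.false_alarm + self.correct_rejection

    def _require_rows(self) -> None:
        if self.n_signal == 0 or self.n_noise == 0:
            raise ValueError(
                "rate computation requires at least one signal and one noise "
                f"observation (got {self.n_signal} signal, {self.n_noise} noise)"
            )


@dataclass(frozen=True)
class SDTResult:
    """Corrected rates and the derived signal-detection indices."""

    hit_rate: float
    fa_rate: float
    dprime: float
    beta: float
    criterion: float


class BinaryROC(NamedTuple):
    auc: float
    points: np.ndarray  # (3, 2) array of (false-positive, true-positive) pairs


@dataclass(frozen=True)
class ScoreSample:
    """Binary signal/noise labels with aligned real-valued scores."""

    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels).astype(bool)
        scores = np.asarray(self.scores, dtype=float)
        if labels.shape != scores.shape or labels.ndim != 1:
            raise ValueError("labels and scores must be aligned 1-d sequences")
        if not labels.any() or labels.all():
            raise ValueError("need at least one signal and one noise observation")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "scores", scores)

    @property
    def cases(self) -> np.ndarray:
        return self.scores[self.labels]

    @property
    def controls(self) -> np.ndarray:
        return self.scores[~self.labels]


@dataclass(frozen=True)
class DeLongResult:
    aucA: float
    aucB: float
    D: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# contingency-table statistics


def corrected_rates(counts: ContingencyCounts) -> tuple[float, float]:
    """Log-linear corrected (hit rate, false-alarm rate), strictly in (0, 1)."""
    counts._require_rows()
    H = (counts.hit + 0.5) / (counts.n_signal + 1)
    F = (counts.false_alarm + 0.5) / (counts.n_noise + 1)
    return H, F


def sdt_statistics(counts: ContingencyCounts) -> SDTResult:
    """d-prime, beta and criterion from one contingency cell."""
    H, F = corrected_rates(counts)
    zH = stats.norm.ppf(H)
    zF = stats.norm.ppf(F)
    dprime = zH - zF
    criterion = -(zH + zF) / 2.0
    beta = np.exp((zF**2 - zH**2) / 2.0)
    return SDTResult(
        hit_rate=H, fa_rate=F, dprime=float(dprime), beta=float(beta),
        criterion=float(criterion),
    )


def binary_auc(counts: ContingencyCounts) -> BinaryROC:
    """AUC of the single-threshold (binary decision) ROC, ties counted one-half.

    Uses the *uncorrected* rates h = hit / (hit + miss) and f = false_alarm /
    (false_alarm + correct_rejection); the ROC has the three points (0, 0),
    (f, h), (1, 1) and area ``(1 + h - f) / 2``.
    """
    counts._require_rows()
    h = counts.hit / counts.n_signal
    f = counts.false_alarm / counts.n_noise
    auc = (1.0 + h - f) / 2.0
    points = np.array([[0.0, 0.0], [f, h], [1.0, 1.0]])
    return BinaryROC(auc=float(auc), points=points)


def counts_to_scores(counts: ContingencyCounts) -> ScoreSample:
    """Per-observation 0/1 scores reconstructed from a contingency cell."""
    counts._require_rows()
    labels = np.concatenate(
        [np.ones(counts.n_signal, dtype=bool), np.zeros(counts.n_noise, dtype=bool)]
    )
    scores = np.concatenate(
        [
            np.ones(counts.hit),
            np.zeros(counts.miss),
            np.ones(counts.false_alarm),
            np.zeros(counts.correct_rejection),
        ]
    )
    return ScoreSample(labels=labels, scores=scores)


# ---------------------------------------------------------------------------
# AUC comparison


def _placements(sample: ScoreSample) -> tuple[float, np.ndarray, np.ndarray]:
    """Midrank AUC and the DeLong structural components (V10, V01)."""
    cases = sample.cases
    controls = sample.controls
    m, n = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    ranks = stats.rankdata(all_scores)
    r_cases = stats.rankdata(cases)
    r_controls = stats.rankdata(controls)
    V10 = (ranks[:m] - r_cases) / n
    V01 = 1.0 - (ranks[m:] - r_controls) / m
    theta = float(V10.mean())
    return theta, V10, V01


def auc(sample: ScoreSample) -> float:
    """Mann-Whitney (midrank) AUC estimate in [0, 1]."""
    return _placements(sample)[0]


def delong_unpaired(
    a: ScoreSample, b: ScoreSample, *, reference: str = "t"
) -> DeLongResult:
    """Unpaired DeLong comparison of two AUCs.

    The variance of each AUC comes from the empirical variances of the
    DeLong structural components over signal and noise placements.  The
    statistic ``D = (aucA - aucB) / sqrt(varA + varB)`` is referred to a t
    distribution with Welch-Satterthwaite degrees of freedom (matching the
    fractional df printed by the standard implementation); ``reference=
    "normal"`` selects a standard-normal reference instead.
    """
    if reference not in ("t", "normal"):
        raise ValueError(f"reference must be 't' or 'normal', got {reference!r}")
    thA, V10A, V01A = _placements(a)
    thB, V10B, V01B = _placements(b)
    varA = np.var(V10A, ddof=1) / len(V10A) + np.var(V01A, ddof=1) / len(V01A)
    varB = np.var(V10B, ddof=1) / len(V10B) + np.var(V01B, ddof=1) / len(V01B)
    diff = thA - thB
    var = varA + varB
    nA = len(V10A) + len(V01A)
    nB = len(V10B) + len(V01B)
    if var == 0.0:
        D = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
        df = float(nA + nB - 2)
        return DeLongResult(aucA=thA, aucB=thB, D=float(D), df=df, p=float(p))
    D = diff / np.sqrt(var)
    df = var**2 / (varA**2 / (nA - 1) + varB**2 / (nB - 1))
    if reference == "t":
        p = 2.0 * stats.t.sf(abs(D), df)
    else:
        p = 2.0 * stats.norm.sf(abs(D))
    return DeLongResult(aucA=thA, aucB=thB, D=float(D), df=float(df), p=float(p))


def bootstrap_auc_test(
    a: ScoreSample,
    b: ScoreSample,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> DeLongResult:
    """Stratified-bootstrap comparison of two AUCs (independent of DeLong).

    Cases and controls of each sample are resampled with replacement
    ``n_boot`` times; the observed AUC difference divided by the bootstrap
    standard deviation of the difference is referred to a standard normal.
    """
    rng = np.random.default_rng(seed)
    aucA, aucB = auc(a), auc(b)

    def boot_aucs(sample: ScoreSample) -> np.ndarray:
        cases, controls = sample.cases, sample.controls
        m, n = len(cases), len(controls)
        ci = rng.integers(0, m, size=(n_boot, m))
        di = rng.integers(0, n, size=(n_boot, n))
        boot = np.concatenate([cases[ci], controls[di]], axis=1)
        ranks = stats.rankdata(boot, axis=1)
        return (ranks[:, :m].sum(axis=1) - m * (m + 1) / 2.0) / (m * n)

    diffs = boot_aucs(a) - boot_aucs(b)
    sd = diffs.std(ddof=1)
    diff = aucA - aucB
    if sd == 0.0:
        D = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        D = diff / sd
        p = 2.0 * stats.norm.sf(abs(D))
    return DeLongResult(
        aucA=aucA, aucB=aucB, D=float(D), df=float("nan"), p=float(p)
    )


# ---------------------------------------------------------------------------
# session records


@dataclass(frozen=True)
class SessionRecord:
    """One mating-trial session: a single female/male pair in a Petri dish."""

    female_species: str
    male_species: str
    year: str
    n_attempts: int
    n_rejections: int
    copulated: bool

    def __post_init__(self) -> None:
        if self.n_attempts < 0 or self.n_rejections < 0:
            raise ValueError("attempt and rejection counts must be non-negative")
        if self.n_rejections > self.n_attempts:
            raise ValueError("cannot have more rejections than attempts")


def sessions_to_counts(
    sessions: Iterable[SessionRecord], behavior: str
) -> dict[tuple[str, str], ContingencyCounts]:
    """Aggregate sessions into contingency counts per (species, year).

    For ``male_mating_attempt`` the unit is the session and the species is
    the male's: a conspecific pairing is the correct signal, and a hit is a
    conspecific session containing at least one attempt.  For
    ``female_rejection`` the unit is the attempt and the species is the
    female's: a heterospecific male is the correct signal, and a hit is a
    rejection of a heterospecific attempt (rejecting a conspecific is a
    false alarm).
    """
    if behavior not in BEHAVIORS:
        raise ValueError(f"behavior must be one of {BEHAVIORS}, got {behavior!r}")
    cells: dict[tuple[str, str], list[int]] = {}
    for s in sessions:
        conspecific = s.female_species == s.male_species
        if behavior == "male_mating_attempt":
            key = (s.male_species, s.year)
            tallies = cells.setdefault(key, [0, 0, 0, 0])
            attempted = s.n_attempts > 0
            if conspecific:
                tallies[0 if attempted else 1] += 1
            else:
                tallies[2 if attempted else 3] += 1
        else:
            key = (s.female_species, s.year)
            tallies = cells.setdefault(key, [0, 0, 0, 0])
            accepted = s.n_attempts - s.n_rejections
            if conspecific:
                tallies[2] += s.n_rejections
                tallies[3] += accepted
            else:
                tallies[0] += s.n_rejections
                tallies[1] += accepted
    return {
        (species, year): ContingencyCounts(
            hit=t[0],
            miss=t[1],
            false_alarm=t[2],
            correct_rejection=t[3],
            behavior=behavior,
            species=species,
            year=year,
        )
        for (species, year), t in sorted(cells.items())
    }


# ---------------------------------------------------------------------------
# I/O

_COUNT_COLUMNS = [
    "behavior",
    "year",
    "species",
    "hit",
    "miss",
    "false_alarm",
    "correct_rejection",
]

_SESSION_COLUMNS = [
    "female_species",
    "male_species",
    "year",
    "n_attempts",
    "n_rejections",
    "copulated",
]


def read_counts_csv(path: str | Path) -> list[ContingencyCounts]:
    """Read a contingency-counts CSV (columns as written by the fixtures)."""
    df = pd.read_csv(path, dtype={"year": str})
    missing = set(_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts file {path} lacks columns {sorted(missing)}")
    return [
        ContingencyCounts(
            hit=int(row.hit),
            miss=int(row.miss),
            false_alarm=int(row.false_alarm),
            correct_rejection=int(row.correct_rejection),
            behavior=row.behavior,
            species=row.species,
            year=str(row.year),
        )
        for row in df.itertuples()
    ]


def read_sessions_csv(path: str | Path) -> list[SessionRecord]:
    df = pd.read_csv(path, dtype={"year": str})
    missing = set(_SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sessions file {path} lacks columns {sorted(missing)}")
    return [
        SessionRecord(
            female_species=row.female_species,
            male_species=row.male_species,
            year=str(row.year),
            n_attempts=int(row.n_attempts),
            n_rejections=int(row.n_rejections),
            copulated=bool(int(row.copulated)),
        )
        for row in df.itertuples()
    ]


def load_packaged_counts() -> list[ContingencyCounts]:
    """The packaged ladybird behaviour counts (both years, both behaviours)."""
    from importlib.resources import files

    return read_counts_csv(files("cspcoex.data") / "behavior_counts.csv")
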