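"""Simulated-annealing peptide design.

The designer walks sequence space with substitution/swap moves, accepting
proposals by the Metropolis criterion under a decaying temperature, and
archives the best unique sequences it encounters.  Objectives are
scalarised and minimised (lower score = stronger predicted affinity):

- ``single``       score of one material
- ``promiscuous``  mean score over a material set
- ``selective``    score(target) - score(off_target)

Scorers are plain callables mapping a (B, L) index array to (B,) scores, so
a trained surrogate, a synthetic ground-truth landscape or any ad-hoc
function plugs in interchangeably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .alphabet import CANONICAL, Alphabet
from .sequences import DEFAULT_LENGTH, Peptide, mutate_indices, write_fasta

Scorer = Callable[[np.ndarray], np.ndarray]

__all__ = [
    "Objective",
    "AnnealSchedule",
    "DesignRun",
    "DesignArchive",
    "objective_value",
    "metropolis_accept",
    "run_annealing",
    "run_campaign",
]


@dataclass(frozen=True)
class Objective:
    """A design goal over one or more materials."""

    mode: str  # single | promiscuous | selective
    materials: tuple[str, ...]

    def __post_init__(self) -> None:
        mats = tuple(self.materials)
        object.__setattr__(self, "materials", mats)
        if self.mode == "single":
            if len(mats) != 1:
                raise ValueError("single objective takes exactly one material")
        elif self.mode == "promiscuous":
            if len(mats) < 2:
                raise ValueError("promiscuous objective takes >= 2 materials")
        elif self.mode == "selective":
            if len(mats) != 2:
                raise ValueError(
                    "selective objective takes exactly (target, off_target)"
                )
        else:
            raise ValueError(f"unknown objective mode {self.mode!r}")


def _check_scorers(scorers: Mapping[str, Scorer], objective: Objective) -> None:
    missing = [m for m in objective.materials if m not in scorers]
    if missing:
        raise KeyError(f"no scorer for material(s) {missing}")


def objective_values(
    scorers: Mapping[str, Scorer], objective: Objective, idx: np.ndarray
) -> np.ndarray:
    """Objective values (lower is better) for a (B, L) index batch."""
    _check_scorers(scorers, objective)
    idx = np.atleast_2d(np.asarray(idx))
    if objective.mode == "single":
        return np.asarray(scorers[objective.materials[0]](idx), dtype=float)
    if objective.mode == "promiscuous":
        per = [np.asarray(scorers[m](idx), dtype=float) for m in objective.materials]
        return np.mean(per, axis=0)
    target, off = objective.materials
    return np.asarray(scorers[target](idx), dtype=float) - np.asarray(
        scorers[off](idx), dtype=float
    )


def objective_value(
    scorers: Mapping[str, Scorer],
    objective: Objective,
    peptide: str,
    alphabet: Alphabet = CANONICAL,
) -> float:
    """Objective value of a single peptide."""
    return float(objective_values(scorers, objective, alphabet.to_indices(peptide)[None, :])[0])


def metropolis_accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept a move with objective change ``delta`` at ``temperature``.

    Downhill and neutral moves (delta <= 0) are always accepted; uphill
    moves with probability exp(-delta / T).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta <= 0:
        return True
    return rng.random() < np.exp(-delta / temperature)


@dataclass(frozen=True)
class AnnealSchedule:
    """Proposal budget and cooling law.

    The default budget of 21 525 attempted mutations per run matches the
    campaign bookkeeping this package reproduces.  Temperatures are in
    score units; the default exponential decay runs from a few score
    standard deviations (exploration) down to far below them (freezing).
    """

    steps: int = 21525
    t_initial: float = 5.0
    t_final: float = 0.05
    decay: str = "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.t_initial <= 0 or self.t_final <= 0:
            raise ValueError("temperatures must be positive")
        if self.t_final > self.t_initial:
            raise ValueError("t_final must not exceed t_initial")
        if self.decay not in ("exponential", "linear"):
            raise ValueError(f"unknown decay {self.decay!r}")

    def temperature(self, step: int) -> float:
        """Temperature at attempt ``step`` (0-based)."""
        if self.steps == 1:
            return self.t_initial
        frac = step / (self.steps - 1)
        if self.decay == "exponential":
            return float(self.t_initial * (self.t_final / self.t_initial) ** frac)
        return float(self.t_initial + (self.t_final - self.t_initial) * frac)


@dataclass
class DesignRun:
    """Trajectory summary and archive of one annealing run."""

    seed: int
    objective_trace: np.ndarray  # objective of the current state per step
    temperature_trace: np.ndarray
    accepted: np.ndarray  # bool per step
    best_so_far: np.ndarray  # non-increasing
    archive: list[tuple[Peptide, float]]  # unique, ascending objective
    archive_steps: list[int]  # step at which each archived value was found
    final_peptide: Peptide

    @property
    def best_value(self) -> float:
        return self.archive[0][1]

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())


@dataclass
class DesignArchive:
    """Merged, deduplicated designs across a campaign.

    ``entries`` rows: (sequence, objective value, run id, step first seen at
    that value), sorted ascending by value with unique sequences.
    """

    entries: list[tuple[Peptide, float, int, int]]
    per_run_best: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def peptides(self) -> list[Peptide]:
        return [e[0] for e in self.entries]

    @property
    def values(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries])

    def top(self, k: int) -> "DesignArchive":
        return DesignArchive(self.entries[:k], self.per_run_best)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.entries, columns=["sequence", "objective", "run", "step"]
        )
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df

    def to_tsv(self, path, scorers: Mapping[str, Scorer] | None = None,
               alphabet: Alphabet = CANONICAL) -> None:
        """Write the archive as TSV; with ``scorers`` given, append one
        predicted-score column per material."""
        df = self.to_frame()
        if scorers and len(df):
            idx = np.stack([alphabet.to_indices(s) for s in df["sequence"]])
            for label, fn in scorers.items():
                df[f"score_{label}"] = np.asarray(fn(idx), dtype=float)
        df.to_csv(path, sep="\t", index=False)

    def to_fasta(self, path) -> None:
        write_fasta(
            [(f"design_{i + 1}|objective={v:.3f}", s)
             for i, (s, v, _, _) in enumerate(self.entries)],
            path,
        )


def run_annealing(
    scorers: Mapping[str, Scorer],
    objective: Objective,
    schedule: AnnealSchedule,
    start: str | None = None,
    length: int = DEFAULT_LENGTH,
    alphabet: Alphabet = CANONICAL,
    p_substitution: float = 0.5,
    archive_cap: int = 1000,
    log_every: int = 0,
) -> DesignRun:
    """One simulated-annealing run.

    Starts from a uniformly random sequence (or ``start``), attempts exactly
    ``schedule.steps`` mutations, and archives the best ``archive_cap``
    unique sequences evaluated along the way.  Reproducible for a fixed
    schedule seed.  With ``log_every`` > 0, progress (step, temperature,
    objective, acceptance rate) is logged at that cadence.
    """
    _check_scorers(scorers, objective)
    rng = np.random.default_rng(schedule.seed)
    if start is None:
        current = rng.integers(len(alphabet), size=length).astype(np.uint8)
    else:
        current = alphabet.to_indices(start)
        length = len(current)
    current_value = float(objective_values(scorers, objective, current[None, :])[0])

    seen: dict[bytes, tuple[float, int]] = {current.tobytes(): (current_value, 0)}
    obj_trace = np.empty(schedule.steps)
    temp_trace = np.empty(schedule.steps)
    accepted = np.zeros(schedule.steps, dtype=bool)
    best_curve = np.empty(schedule.steps)
    best = current_value
    for step in range(schedule.steps):
        T = schedule.temperature(step)
        proposal = mutate_indices(current, rng, p_substitution, n_letters=len(alphabet))
        value = float(objective_values(scorers, objective, proposal[None, :])[0])
        key = proposal.tobytes()
        prev = seen.get(key)
        if prev is None or value < prev[0]:
            seen[key] = (value, step)
        if metropolis_accept(value - current_value, T, rng):
            current, current_value = proposal, value
            accepted[step] = True
        best = min(best, value)
        obj_trace[step] = current_value
        temp_trace[step] = T
        best_curve[step] = best
        if log_every and (step + 1) % log_every == 0:
            logger.info(
                "step %d/%d T=%.4g objective=%.3f best=%.3f acceptance=%.3f",
                step + 1, schedule.steps, T, current_value, best,
                accepted[: step + 1].mean(),
            )

    ranked = sorted(seen.items(), key=lambda kv: (kv[1][0], kv[0]))[:archive_cap]
    archive = [
        (Peptide(alphabet.to_sequence(np.frombuffer(k, dtype=np.uint8))), v)
        for k, (v, _) in ranked
    ]
    return DesignRun(
        seed=schedule.seed,
        objective_trace=obj_trace,
        temperature_trace=temp_trace,
        accepted=accepted,
        best_so_far=best_curve,
        archive=archive,
        archive_steps=[s for _, (_, s) in ranked],
        final_peptide=Peptide(alphabet.to_sequence(current)),
    )


def run_campaign(
    scorers: Mapping[str, Scorer],
    objective: Objective,
    schedule: AnnealSchedule,
    n_runs: int = 55,
    base_seed: int = 0,
    length: int = DEFAULT_LENGTH,
    alphabet: Alphabet = CANONICAL,
    p_substitution: float = 0.5,
    archive_cap: int = 1000,
) -> DesignArchive:
    """Run ``n_runs`` independent annealing runs (seeds ``base_seed + i``)
    and merge their archives, keeping the best value per unique sequence."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    merged: dict[str, tuple[float, int, int]] = {}
    per_run_best: list[float] = []
    for run_id in range(n_runs):
        run_schedule = AnnealSchedule(
            steps=schedule.steps,
            t_initial=schedule.t_initial,
            t_final=schedule.t_final,
            decay=schedule.decay,
            seed=base_seed + run_id,
        )
        try:
            run = run_annealing(
                scorers, objective, run_schedule,
                length=length, alphabet=alphabet,
                p_substitution=p_substitution, archive_cap=archive_cap,
            )
        except Exception as exc:
            raise RuntimeError(f"annealing run {run_id} failed: {exc}") from exc
        per_run_best.append(run.best_value)
        for (seq, value), step in zip(run.archive, run.archive_steps):
            kept = merged.get(seq)
            if kept is None or value < kept[0]:
                merged[seq] = (value, run_id, step)
    entries = sorted(
        ((Peptide(s), v, rid, st) for s, (v, rid, st) in merged.items()),
        key=lambda e: (e[1], e[0]),
    )
    return DesignArchive(entries=entries, per_run_best=per_run_best)
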