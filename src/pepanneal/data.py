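"""Sequence-score tables: loading, splitting and top-k summaries.

A :class:`ScoreTable` holds (peptide, score) records for one material.
Scores follow the lower-is-better convention of biophysical affinity
scores: a more negative score means stronger predicted binding.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import CANONICAL, Alphabet
from .sequences import Peptide, validate_peptide


@dataclass(frozen=True)
class ScoreSummary:
    """Mean, sample standard deviation and minimum over the k best scores."""

    k: int
    mean: float
    std: float
    minimum: float


@dataclass
class ScoreTable:
    """(sequence, score) records for a single material.

    ``df`` has columns ``sequence`` (str) and ``score`` (float); all
    sequences share one length.
    """

    material_label: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.material_label:
            raise ValueError("material_label must be non-empty")
        if list(self.df.columns[:2]) != ["sequence", "score"]:
            raise ValueError("ScoreTable frame needs columns ['sequence', 'score']")
        if len(self.df):
            lengths = self.df["sequence"].str.len()
            if lengths.nunique() != 1:
                raise ValueError("all peptides in a table must share one length")
            if not np.isfinite(self.df["score"]).all():
                raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def peptide_length(self) -> int:
        if not len(self.df):
            raise ValueError("empty table has no peptide length")
        return len(self.df["sequence"].iloc[0])

    @property
    def sequences(self) -> list[str]:
        return self.df["sequence"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)

    @classmethod
    def from_records(cls, material_label: str, records) -> "ScoreTable":
        df = pd.DataFrame(records, columns=["sequence", "score"])
        df["score"] = df["score"].astype(float)
        return cls(material_label, df)

    def to_csv(self, path, sep: str = "\t") -> None:
        self.df.to_csv(path, sep=sep, index=False)


def load_table(
    path,
    material_label: str,
    sequence_column: str = "sequence",
    score_column: str = "score",
    sep: str | None = None,
    length: int | None = None,
    alphabet: Alphabet = CANONICAL,
    deduplicate: bool = True,
) -> ScoreTable:
    """Load a delimited sequence-score table.

    The delimiter is sniffed when ``sep`` is None, and a header line is
    auto-detected (a file may also be headerless with sequence and score as
    the first two columns).  Duplicate sequences are optionally collapsed
    keeping the best (lowest) score.  Invalid rows raise with their 1-based
    row number.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: empty table")
    first = text.splitlines()[0]
    if sep is None:
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    fields = [f.strip() for f in first.split(sep)]

    def _is_number(s: str) -> bool:
        try:
            float(s.replace("−", "-"))
            return True
        except ValueError:
            return False

    has_header = not any(_is_number(f) for f in fields)
    if has_header:
        df = pd.read_csv(io.StringIO(text), sep=sep)
        if sequence_column not in df.columns or score_column not in df.columns:
            raise ValueError(
                f"{path}: expected columns {sequence_column!r} and {score_column!r}, "
                f"found {list(df.columns)}"
            )
        df = df[[sequence_column, score_column]]
    else:
        df = pd.read_csv(io.StringIO(text), sep=sep, header=None).iloc[:, :2]
    df.columns = ["sequence", "score"]

    records: list[tuple[Peptide, float]] = []
    for row_number, (seq, raw_score) in enumerate(
        zip(df["sequence"], df["score"]), start=1 + int(has_header)
    ):
        if isinstance(raw_score, str):
            raw_score = raw_score.replace("−", "-")
        try:
            score = float(raw_score)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: unparseable score {raw_score!r} at row {row_number}"
            ) from exc
        if not np.isfinite(score):
            raise ValueError(f"{path}: non-finite score at row {row_number}")
        try:
            pep = validate_peptide(
                str(seq),
                length=length if length is not None else len(str(seq).strip()),
                alphabet=alphabet,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_number}: {exc}") from exc
        records.append((pep, score))

    out = pd.DataFrame(records, columns=["sequence", "score"])
    if deduplicate:
        out = (
            out.sort_values(["sequence", "score"], kind="mergesort")
            .drop_duplicates("sequence", keep="first")
            .reset_index(drop=True)
        )
    return ScoreTable(material_label, out)


def split_table(
    table: ScoreTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[ScoreTable, ScoreTable, ScoreTable]:
    """Random disjoint train/validation/test partition by record.

    Sizes are the rounded fractions (train absorbs rounding remainder);
    identical seed gives an identical split.
    """
    f_train, f_val, f_test = fractions
    if not all(0 < f < 1 for f in fractions):
        raise ValueError("each fraction must lie in (0, 1)")
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(table)
    if n == 0:
        raise ValueError("cannot split an empty table")
    n_val = int(round(n * f_val))
    n_test = int(round(n * f_test))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("fractions leave a negative part size")
    perm = np.random.default_rng(seed).permutation(n)
    parts = (
        perm[:n_train],
        perm[n_train : n_train + n_val],
        perm[n_train + n_val :],
    )
    return tuple(
        ScoreTable(table.material_label, table.df.iloc[np.sort(p)].reset_index(drop=True))
        for p in parts
    )


def summarize_top(table: ScoreTable, k: int) -> ScoreSummary:
    """Mean +/- sample std (minimum) over the k lowest-score records.

    Ties at the k-th rank are broken by lexicographic sequence order so the
    summary is deterministic.
    """
    n = len(table)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds table size {n}")
    top = (
        table.df.sort_values(["score", "sequence"], kind="mergesort")
        .head(k)["score"]
        .to_numpy(dtype=float)
    )
    std = float(np.std(top, ddof=1)) if k > 1 else 0.0
    return ScoreSummary(k=k, mean=float(top.mean()), std=std, minimum=float(top.min()))


def export_summaries(rows, path, sep: str = "\t") -> None:
    """Write campaign summaries as a small table.

    ``rows`` is an iterable of (label, novelty, ScoreSummary); columns are
    label, novelty, mean, std, minimum.
    """
    df = pd.DataFrame(
        [
            {"label": label, "novelty": nov, "mean": s.mean,
             "std": s.std, "minimum": s.minimum}
            for label, nov, s in rows
        ]
    )
    df.to_csv(path, sep=sep, index=False)
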