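"""Synthetic sequence-score landscapes.

A landscape assigns each fixed-length peptide a deterministic score

    score(a_1..a_L) = offset + sum_i W[i, a_i] + sum_(i,j) C_ij[a_i, a_j]

with per-position additive weights ``W`` and a sparse set of pairwise
coupling matrices ``C_ij`` (mild epistasis), optionally observed with
Gaussian noise.  Weights are row-centred so a uniformly random peptide
scores ``offset`` in expectation, with standard deviation approximately
``weight_scale * sqrt(L)``.  Defaults put scores in the -80..-20 band
typical of biophysical peptide-affinity scores (mean around -40), so
summaries are directly comparable with real score tables.

These landscapes serve as ground-truth oracles for training and design
experiments: every dataset in the test-suite is generated from one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alphabet import CANONICAL, Alphabet
from .data import ScoreTable
from .sequences import encode_batch


@dataclass
class SyntheticLandscape:
    """Additive-plus-pairwise ground-truth scoring function."""

    label: str
    position_weights: np.ndarray  # (L, A) float64
    couplings: list[tuple[int, int, np.ndarray]] = field(default_factory=list)
    offset: float = -40.0
    noise_sigma: float = 0.0
    seed: int = 0
    alphabet: Alphabet = CANONICAL

    def __post_init__(self) -> None:
        self.position_weights = np.asarray(self.position_weights, dtype=float)
        if self.position_weights.shape[1] != len(self.alphabet):
            raise ValueError("position_weights second dimension must match alphabet")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        L = self.length
        for i, j, mat in self.couplings:
            if not (0 <= i < j < L):
                raise ValueError(f"invalid coupling pair ({i}, {j})")
            if np.shape(mat) != (len(self.alphabet), len(self.alphabet)):
                raise ValueError("coupling matrices must be A x A")

    @property
    def length(self) -> int:
        return self.position_weights.shape[0]

    # -- scoring ------------------------------------------------------------

    def score_indices(self, idx: np.ndarray) -> np.ndarray:
        """Deterministic scores for a (B, L) index array."""
        idx = np.atleast_2d(np.asarray(idx))
        if idx.shape[1] != self.length:
            raise ValueError(f"expected length {self.length}, got {idx.shape[1]}")
        s = self.position_weights[np.arange(self.length), idx].sum(axis=1)
        for i, j, mat in self.couplings:
            s = s + np.asarray(mat)[idx[:, i], idx[:, j]]
        return s + self.offset

    def score(
        self,
        peptide: str,
        with_noise: bool = False,
        rng: np.random.Generator | None = None,
    ) -> float:
        """Score one peptide; optionally add observation noise."""
        value = float(self.score_indices(self.alphabet.to_indices(peptide)[None, :])[0])
        if with_noise and self.noise_sigma > 0:
            if rng is None:
                raise ValueError("noisy scoring requires an rng")
            value += float(rng.normal(0.0, self.noise_sigma))
        return value

    def scorer(self):
        """Batch scorer callable (index array -> scores) for the annealer."""
        return self.score_indices

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "alphabet": self.alphabet.letters,
                "offset": self.offset,
                "noise_sigma": self.noise_sigma,
                "seed": self.seed,
                "position_weights": self.position_weights.tolist(),
                "couplings": [
                    {"i": i, "j": j, "matrix": np.asarray(m).tolist()}
                    for i, j, m in self.couplings
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticLandscape":
        d = json.loads(text)
        return cls(
            label=d["label"],
            position_weights=np.array(d["position_weights"]),
            couplings=[
                (c["i"], c["j"], np.array(c["matrix"])) for c in d["couplings"]
            ],
            offset=d["offset"],
            noise_sigma=d["noise_sigma"],
            seed=d["seed"],
            alphabet=Alphabet(d["alphabet"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SyntheticLandscape":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class LandscapeFamily:
    """Landscapes for several pseudo-materials with controlled pairwise
    correlation between their additive components."""

    landscapes: list[SyntheticLandscape]
    target_correlation: float = 0.0

    def __post_init__(self) -> None:
        lengths = {ls.length for ls in self.landscapes}
        alphabets = {ls.alphabet.letters for ls in self.landscapes}
        if len(lengths) != 1 or len(alphabets) != 1:
            raise ValueError("family members must share length and alphabet")

    def __iter__(self):
        return iter(self.landscapes)

    def __getitem__(self, i: int) -> SyntheticLandscape:
        return self.landscapes[i]

    def labels(self) -> list[str]:
        return [ls.label for ls in self.landscapes]

    def scorers(self) -> dict:
        return {ls.label: ls.scorer() for ls in self.landscapes}


def _centered_weights(rng, shape: tuple[int, ...], scale: float) -> np.ndarray:
    w = rng.normal(0.0, scale, size=shape)
    return w - w.mean(axis=-1, keepdims=True)


def make_landscape(
    seed: int,
    L: int = 12,
    n_couplings: int = 6,
    weight_scale: float = 2.0,
    offset: float = -40.0,
    noise_sigma: float = 0.0,
    label: str = "synthetic",
    alphabet: Alphabet = CANONICAL,
) -> SyntheticLandscape:
    """Draw a random landscape.

    Additive weights are N(0, weight_scale) per (position, letter),
    centred per position; couplings sit on ``n_couplings`` random position
    pairs with scale ``weight_scale / 4`` (mild epistasis that separates
    sequence models from purely linear fits without making the landscape
    unlearnable).
    """
    if L < 1 or weight_scale < 0 or noise_sigma < 0:
        raise ValueError("invalid landscape parameters")
    max_pairs = L * (L - 1) // 2
    if n_couplings > max_pairs:
        raise ValueError(f"n_couplings={n_couplings} exceeds {max_pairs} pairs")
    rng = np.random.default_rng(seed)
    A = len(alphabet)
    weights = _centered_weights(rng, (L, A), weight_scale)
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    chosen = rng.choice(len(pairs), size=n_couplings, replace=False) if n_couplings else []
    couplings = []
    for p in chosen:
        i, j = pairs[int(p)]
        mat = rng.normal(0.0, weight_scale / 4.0, size=(A, A))
        couplings.append((i, j, mat - mat.mean()))
    return SyntheticLandscape(
        label=label,
        position_weights=weights,
        couplings=couplings,
        offset=offset,
        noise_sigma=noise_sigma,
        seed=seed,
        alphabet=alphabet,
    )


def make_family(
    k: int = 5,
    target_correlation: float = 0.0,
    shared_seed: int = 0,
    L: int = 12,
    n_couplings: int = 6,
    weight_scale: float = 2.0,
    offset: float = -40.0,
    noise_sigma: float = 0.0,
    labels: list[str] | None = None,
    alphabet: Alphabet = CANONICAL,
) -> LandscapeFamily:
    """Construct k landscapes whose additive components correlate pairwise
    at ``target_correlation``.

    For rho >= 0 members share a common component:
    ``W_m = sqrt(rho) * S + sqrt(1 - rho) * E_m`` (every pair correlates at
    rho).  A negative rho is only well-posed for k = 2, where
    ``W_0 = S`` and ``W_1 = rho * S + sqrt(1 - rho^2) * E`` give exactly rho.
    Couplings (and noise) are independent per member, so empirical score
    correlations are mildly attenuated toward 0.
    """
    rho = float(target_correlation)
    if k < 2:
        raise ValueError("a family needs at least 2 members")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("target_correlation must lie in [-1, 1]")
    if rho < 0 and k != 2:
        raise ValueError("negative correlation is only well-posed for k = 2")
    if labels is None:
        labels = [f"mat{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("need one label per member")
    rng = np.random.default_rng(shared_seed)
    A = len(alphabet)
    shared = _centered_weights(rng, (L, A), weight_scale)
    members = []
    for m in range(k):
        ls = make_landscape(
            seed=int(rng.integers(2**31)),
            L=L,
            n_couplings=n_couplings,
            weight_scale=weight_scale,
            offset=offset,
            noise_sigma=noise_sigma,
            label=labels[m],
            alphabet=alphabet,
        )
        own = ls.position_weights
        if rho >= 0:
            ls.position_weights = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        elif m == 0:
            ls.position_weights = shared
        else:
            ls.position_weights = rho * shared + np.sqrt(1 - rho**2) * own
        members.append(ls)
    return LandscapeFamily(members, target_correlation=rho)


def random_indices(
    rng: np.random.Generator, n: int, L: int, alphabet: Alphabet = CANONICAL
) -> np.ndarray:
    return rng.integers(len(alphabet), size=(n, L)).astype(np.uint8)


def generate_dataset(
    landscape: SyntheticLandscape,
    n: int,
    seed: int,
    sampling: str = "uniform",
    greedy_steps: int = 5,
) -> ScoreTable:
    """Sample ``n`` unique sequences with noisy oracle scores.

    ``sampling="uniform"`` draws sequences uniformly at random.
    ``sampling="biased"`` takes ``greedy_steps`` greedy substitution steps
    from each uniform start, accepting improvements only, which enriches
    low-score sequences the way score-optimizing trajectory data does.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    L, A = landscape.length, len(landscape.alphabet)
    space = A**L if L * np.log(A) < 40 else None
    if space is not None and n > space:
        raise ValueError(f"n={n} exceeds the {space}-sequence space")
    if sampling not in ("uniform", "biased"):
        raise ValueError(f"unknown sampling mode {sampling!r}")
    rng = np.random.default_rng(seed)
    seen: set[bytes] = set()
    rows_idx: list[np.ndarray] = []
    while len(rows_idx) < n:
        batch = random_indices(rng, max(256, int((n - len(rows_idx)) * 1.1)), L,
                               landscape.alphabet)
        if sampling == "biased":
            batch = _greedy_enrich(landscape, batch, rng, greedy_steps)
        for row in batch:
            key = row.tobytes()
            if key not in seen:
                seen.add(key)
                rows_idx.append(row)
                if len(rows_idx) == n:
                    break
    idx = np.stack(rows_idx)
    scores = landscape.score_indices(idx)
    if landscape.noise_sigma > 0:
        scores = scores + rng.normal(0.0, landscape.noise_sigma, size=n)
    seqs = ["".join(landscape.alphabet.letters[c] for c in row) for row in idx]
    return ScoreTable.from_records(landscape.label, list(zip(seqs, scores)))


def _greedy_enrich(
    landscape: SyntheticLandscape,
    idx: np.ndarray,
    rng: np.random.Generator,
    steps: int,
) -> np.ndarray:
    """Vectorised greedy walk: propose one substitution per walker per step,
    keep it where it improves the deterministic score."""
    idx = idx.copy()
    current = landscape.score_indices(idx)
    n, L = idx.shape
    A = len(landscape.alphabet)
    for _ in range(steps):
        pos = rng.integers(L, size=n)
        shift = rng.integers(1, A, size=n)
        proposal = idx.copy()
        rows = np.arange(n)
        proposal[rows, pos] = (idx[rows, pos] + shift) % A
        new = landscape.score_indices(proposal)
        better = new < current
        idx[better] = proposal[better]
        current = np.where(better, new, current)
    return idx


def table_indices(table: ScoreTable, alphabet: Alphabet = CANONICAL) -> np.ndarray:
    """Index-encode a whole ScoreTable (B, L)."""
    return encode_batch(table.sequences, alphabet)
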