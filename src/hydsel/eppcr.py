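"""Error-prone PCR library simulation.

The mutagenesis error model is a substitution spectrum: a per-kilobase
mutation rate mu (the GeneMorph-style "mutations/kb" a kit reports; default
4.5) together with a 4x4 matrix of relative substitution weights, row-indexed
by the reference base.  Per clone the number of substitutions is Poisson with
mean mu*L/1000 (errors are approximately independent per site), truncated at
L; positions are uniform without replacement (a physical base mutates once
per clone); the replacement base is drawn from the spectrum row of the
reference base.

The kit vendor's exact substitution preferences are rarely published, so the
default matrix is uniform over the 12 substitution types; a documented
transition/AT-biased alternative is provided and any matrix can be loaded
from YAML for faithful reproduction of a particular kit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import yaml

from .seqcore import (
    BASES,
    CodingSequence,
    PointMutation,
    ValidationError,
)

DEFAULT_RATE_PER_KB = 4.5


def _as_matrix(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValidationError(f"spectrum matrix must be 4x4, got shape {m.shape}")
    if (m < 0).any() or not np.isfinite(m).all():
        raise ValidationError("spectrum matrix weights must be finite and nonnegative")
    if np.diagonal(m).any():
        raise ValidationError("spectrum matrix diagonal must be zero (no self-substitution)")
    return m


@dataclass(frozen=True)
class MutationSpectrum:
    """Per-kb mutation rate plus a 4x4 substitution-preference matrix.

    Rows/columns are ordered A, C, G, T.  Weights need not be normalized;
    ``normalized_matrix`` renormalizes each row to conditional substitution
    probabilities.  A row may be all zero only if the corresponding base never
    occurs in the sequence being mutagenized (checked when a simulator is
    built).
    """

    rate_per_kb: float = DEFAULT_RATE_PER_KB
    matrix: np.ndarray = field(default_factory=lambda: _uniform_matrix())

    def __post_init__(self) -> None:
        if self.rate_per_kb < 0 or not np.isfinite(self.rate_per_kb):
            raise ValidationError(f"rate_per_kb must be finite and >= 0, got {self.rate_per_kb}")
        object.__setattr__(self, "matrix", _as_matrix(self.matrix))

    @property
    def normalized_matrix(self) -> np.ndarray:
        """Row-normalized matrix; zero rows are left as zero."""
        rowsum = self.matrix.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(rowsum > 0, self.matrix / rowsum, 0.0)
        return norm

    @classmethod
    def uniform(cls, rate_per_kb: float = DEFAULT_RATE_PER_KB) -> "MutationSpectrum":
        """Uniform weight on each of the 12 substitution types (the default)."""
        return cls(rate_per_kb, _uniform_matrix())

    @classmethod
    def eppcr_biased(
        cls, rate_per_kb: float = DEFAULT_RATE_PER_KB, transition_weight: float = 3.0
    ) -> "MutationSpectrum":
        """An illustrative Taq-like biased spectrum.

        Transitions (A<->G, C<->T) are favored ``transition_weight``-fold over
        transversions, the dominant qualitative feature of error-prone PCR
        chemistry.  The values are this package's own and stand in for
        unpublished kit spectra.
        """
        m = np.ones((4, 4)) - np.eye(4)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
            m[i, j] = transition_weight
        return cls(rate_per_kb, m)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MutationSpectrum":
        """Load ``{rate_per_kb: float, matrix: 4x4 rows in ACGT order}``.

        ``matrix`` may be a list of four 4-lists or a mapping of mappings
        keyed by base letters.
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "matrix" not in doc:
            raise ValidationError(f"spectrum file {path}: expected keys rate_per_kb, matrix")
        raw = doc["matrix"]
        if isinstance(raw, dict):
            m = [[float(raw[r].get(c, 0.0)) for c in BASES] for r in BASES]
        else:
            m = raw
        return cls(float(doc.get("rate_per_kb", DEFAULT_RATE_PER_KB)), m)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "rate_per_kb": float(self.rate_per_kb),
            "base_order": list(BASES),
            "matrix": [[float(x) for x in row] for row in self.matrix],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _uniform_matrix() -> np.ndarray:
    return np.ones((4, 4)) - np.eye(4)


def draw_mutation_count(
    spectrum: MutationSpectrum, L: int, rng: np.random.Generator
) -> int:
    """Number of substitutions for one clone: Poisson(mu*L/1000), capped at L."""
    if L < 3:
        raise ValidationError(f"sequence length {L} < 3")
    return int(min(rng.poisson(spectrum.rate_per_kb * L / 1000.0), L))


@dataclass(frozen=True)
class SimulatedVariant:
    """One simulated clone of an epPCR library."""

    parent_id: str
    mutations: tuple[PointMutation, ...]


class LibrarySimulator:
    """Vectorized sampler of epPCR clones from one parent CDS.

    Construction fails if the spectrum row of any base present in the parent
    has zero total weight (such a clone could never acquire a replacement
    base there).
    """

    def __init__(self, seq: CodingSequence, spectrum: MutationSpectrum) -> None:
        self.seq = seq
        self.spectrum = spectrum
        self._seq_idx = seq.base_index_array()
        norm = spectrum.normalized_matrix
        present = np.unique(self._seq_idx)
        dead = [BASES[i] for i in present if norm[i].sum() == 0]
        if dead:
            raise ValidationError(
                f"spectrum row(s) {dead} have zero weight but the base occurs "
                f"in CDS {seq.id!r}"
            )
        cum = np.cumsum(norm, axis=1)
        cum[present, -1] = 1.0  # guard against rounding in the final bin
        self._row_cum = cum

    @property
    def L(self) -> int:
        return len(self.seq)

    def sample_batch_arrays(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sample ``n`` clones as padded arrays.

        Returns ``(ks, pos, alt)`` where ``ks[i]`` is clone i's mutation
        count, ``pos`` is (n, kmax) of 0-based positions and ``alt`` the
        matching base indices; entries beyond ``ks[i]`` are -1.
        """
        L = self.L
        lam = self.spectrum.rate_per_kb * L / 1000.0
        ks = np.minimum(rng.poisson(lam, size=n), L)
        kmax = int(ks.max(initial=0))
        if n == 0 or kmax == 0:
            empty = np.full((n, 0), -1, dtype=np.int64)
            return ks, empty, empty.copy()
        pos = rng.integers(0, L, size=(n, kmax), dtype=np.int64)
        cols = np.arange(kmax)
        pad = cols[None, :] >= ks[:, None]
        # Dense clones (k comparable to L) are sampled by permutation, where
        # rejection would be hopeless.
        dense = np.flatnonzero(ks > L // 4)
        for i in dense:
            k = int(ks[i])
            pos[i, :k] = rng.permutation(L)[:k]
        # Rejection sampling of without-replacement position sets: any clone
        # with an intra-clone duplicate is redrawn wholesale.  Padding slots
        # are masked with unique sentinels so they never trigger a redraw.
        while True:
            work = np.where(pad, L + cols[None, :], pos)
            srt = np.sort(work, axis=1)
            dup = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
            if dup.size == 0:
                break
            pos[dup] = rng.integers(0, L, size=(dup.size, kmax))
        ref = self._seq_idx[pos]
        u = rng.random(size=(n, kmax))
        alt = (u[..., None] >= self._row_cum[ref]).sum(axis=-1)
        pos[pad] = -1
        alt[pad] = -1
        return ks, pos, alt

    def variant_from_row(self, pos_row: np.ndarray, alt_row: np.ndarray, k: int) -> SimulatedVariant:
        muts = tuple(
            sorted(
                (
                    PointMutation(
                        position=int(p) + 1,
                        ref_base=BASES[self._seq_idx[p]],
                        alt_base=BASES[int(a)],
                    )
                    for p, a in zip(pos_row[:k], alt_row[:k])
                ),
                key=lambda m: m.position,
            )
        )
        return SimulatedVariant(parent_id=self.seq.id, mutations=muts)


def mutate_sequence(
    seq: CodingSequence, spectrum: MutationSpectrum, rng: np.random.Generator
) -> SimulatedVariant:
    """Draw one simulated clone."""
    sim = LibrarySimulator(seq, spectrum)
    ks, pos, alt = sim.sample_batch_arrays(1, rng)
    return sim.variant_from_row(pos[0], alt[0], int(ks[0]))


def simulate_library(
    seq: CodingSequence,
    spectrum: MutationSpectrum,
    n: int,
    seed: int,
    chunk_size: int = 2048,
) -> Iterator[SimulatedVariant]:
    """Stream exactly ``n`` simulated clones, reproducible for a given seed.

    Clones are generated in fixed-size chunks internally, so memory use is
    constant in ``n``.
    """
    if n < 0:
        raise ValidationError(f"library size must be >= 0, got {n}")
    sim = LibrarySimulator(seq, spectrum)
    rng = np.random.default_rng(seed)
    remaining = n
    while remaining > 0:
        m = min(chunk_size, remaining)
        ks, pos, alt = sim.sample_batch_arrays(m, rng)
        for i in range(m):
            yield sim.variant_from_row(pos[i], alt[i], int(ks[i]))
        remaining -= m
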