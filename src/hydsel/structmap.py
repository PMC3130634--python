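"""Linear protein-architecture mapping of isolated mutations.

Three analyses annotate where selected mutations fall on the protein:

* truncation analysis — the first in-frame stop introduced by a variant's
  mutations determines how many residues are retained and which named
  domains are lost or disrupted;
* surface windows — per-residue diffusion-accessibility scores are averaged
  in a centered moving window (default 5 residues) and thresholded into
  maximal runs of surface-accessible residues;
* surface clustering — a permutation test asks whether mutated residues fall
  inside the surface regions more often than uniform placement over an
  eligible residue set would predict.

Domain and accessibility tables use 1-based inclusive residue coordinates
(note: *not* BED's 0-based half-open convention), matching how residue
positions are reported in mutant summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    ChargeScheme,
    CodingSequence,
    ValidationError,
    VariantRecord,
    apply_mutations,
)

DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class DomainAnnotation:
    """A named residue interval, 1-based inclusive."""

    name: str
    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_res <= self.end_res:
            raise ValidationError(
                f"domain {self.name!r}: invalid interval "
                f"[{self.start_res}, {self.end_res}]"
            )


@dataclass
class AccessibilityProfile:
    """Per-residue accessibility scores (unitless), index 1..n."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValidationError("accessibility profile must be a nonempty 1-D array")
        if not np.isfinite(self.scores).all():
            raise ValidationError("accessibility profile contains non-finite values")

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class SurfaceRegions:
    """Disjoint sorted residue intervals called surface-accessible."""

    intervals: list[tuple[int, int]]
    threshold: float
    window: int

    def __post_init__(self) -> None:
        last_end = 0
        for a, b in self.intervals:
            if a <= last_end or b < a:
                raise ValidationError(f"intervals not disjoint/sorted at ({a}, {b})")
            last_end = b

    def covers(self, residue: int) -> bool:
        return any(a <= residue <= b for a, b in self.intervals)

    def mask(self, n_residues: int) -> np.ndarray:
        m = np.zeros(n_residues, dtype=bool)
        for a, b in self.intervals:
            m[a - 1 : b] = True
        return m

    @property
    def n_residues(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)


def smooth_profile(
    profile: AccessibilityProfile | np.ndarray, window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Centered moving average; edges average over the truncated window.

    ``window`` must be odd (the center is undefined otherwise) and no longer
    than the profile.
    """
    x = profile.scores if isinstance(profile, AccessibilityProfile) else np.asarray(
        profile, dtype=float
    )
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ValidationError(f"window {window} exceeds profile length {x.size}")
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def threshold_regions(
    smoothed: np.ndarray, threshold: float, window: int = DEFAULT_WINDOW
) -> SurfaceRegions:
    """Maximal runs of residues with smoothed score >= threshold."""
    if np.isnan(threshold) or threshold == np.inf:
        raise ValidationError("threshold must not be +inf/NaN")
    above = np.asarray(smoothed) >= threshold
    intervals: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above, start=1):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, above.size))
    return SurfaceRegions(intervals=intervals, threshold=float(threshold), window=window)


def surface_regions(
    profile: AccessibilityProfile,
    window: int = DEFAULT_WINDOW,
    threshold: Optional[float] = None,
) -> SurfaceRegions:
    """Smooth then threshold; default threshold is the smoothed-profile mean."""
    sm = smooth_profile(profile, window)
    tau = float(np.mean(sm)) if threshold is None else threshold
    return threshold_regions(sm, tau, window)


# ---------------------------------------------------------------------------
# Truncation analysis
# ---------------------------------------------------------------------------


@dataclass
class TruncationReport:
    variant_id: str
    first_stop_codon_index: Optional[int]
    residues_retained: int
    residues_lost: int
    domains_lost: list[str]
    domains_disrupted: list[str]


def truncation_report(
    variant: VariantRecord,
    parent: CodingSequence,
    domains: Sequence[DomainAnnotation] = (),
) -> TruncationReport:
    """Locate the first introduced stop and account for lost residues/domains.

    Scanning the fully mutated CDS 5'->3', a stop at codon index s leaves
    s - 1 residues; the parent's own terminal stop does not count as
    introduced.  A domain is *lost* when it lies entirely at or beyond the
    stop and *disrupted* when the stop falls inside it.
    """
    if variant.parent_id != parent.id:
        raise ValidationError(
            f"variant {variant.variant_id!r} references parent "
            f"{variant.parent_id!r}, not {parent.id!r}"
        )
    full_length = len(parent.protein)
    mutated = apply_mutations(parent, variant.mutations)
    aa = mutated.translate()
    stop_idx: Optional[int] = None
    hit = aa.find("*")
    if 0 <= hit < full_length:  # a stop within the protein-coding span
        stop_idx = hit + 1
    if stop_idx is None:
        retained = full_length
    else:
        retained = stop_idx - 1
    lost = full_length - retained
    domains_lost = [d.name for d in domains if stop_idx is not None and d.start_res >= stop_idx]
    domains_disrupted = [
        d.name
        for d in domains
        if stop_idx is not None and d.start_res < stop_idx <= d.end_res
    ]
    return TruncationReport(
        variant_id=variant.variant_id,
        first_stop_codon_index=stop_idx,
        residues_retained=retained,
        residues_lost=lost,
        domains_lost=domains_lost,
        domains_disrupted=domains_disrupted,
    )


# ---------------------------------------------------------------------------
# Surface clustering permutation test
# ---------------------------------------------------------------------------


@dataclass
class ClusterTestResult:
    observed: int
    n_positions: int
    expected: float
    p_value: float
    n_perm: int


def surface_cluster_test(
    positions: Sequence[int],
    regions: SurfaceRegions,
    n_residues: int,
    eligible: Optional[Sequence[int]] = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusterTestResult:
    """Permutation test for clustering of mutated residues on surface regions.

    The observed statistic is the number of ``positions`` (1-based residues;
    repeats allowed, as one residue can be hit in several variants) falling
    inside ``regions``.  The null redraws the same number of residues
    uniformly, with replacement, from the eligible set (default: all
    residues) ``n_perm`` times; p is the add-one upper tail.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    positions = np.asarray(positions, dtype=int)
    if positions.size and (positions.min() < 1 or positions.max() > n_residues):
        raise ValidationError("mutated positions outside protein bounds")
    elig = (
        np.arange(1, n_residues + 1)
        if eligible is None
        else np.unique(np.asarray(eligible, dtype=int))
    )
    if elig.size == 0:
        raise ValidationError("eligible residue set is empty")
    if elig.min() < 1 or elig.max() > n_residues:
        raise ValidationError("eligible residues outside protein bounds")
    in_region = regions.mask(n_residues)
    observed = int(in_region[positions - 1].sum()) if positions.size else 0
    rng = np.random.default_rng(seed)
    draws = rng.choice(elig, size=(n_perm, positions.size), replace=True)
    perm_counts = (
        in_region[draws - 1].sum(axis=1) if positions.size else np.zeros(n_perm)
    )
    r = int((perm_counts >= observed).sum())
    return ClusterTestResult(
        observed=observed,
        n_positions=int(positions.size),
        expected=float(perm_counts.mean()),
        p_value=(r + 1) / (n_perm + 1),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """3-column TSV: name, start, end (1-based inclusive); header mandatory."""
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "start", "end"):
        if col not in df.columns:
            raise ValidationError(f"domain table {path}: missing column {col!r}")
    return [
        DomainAnnotation(str(r.name), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def write_domains(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [d.name for d in domains],
            "start": [d.start_res for d in domains],
            "end": [d.end_res for d in domains],
        }
    ).to_csv(path, sep="\t", index=False)


def read_accessibility(path: str | Path) -> AccessibilityProfile:
    """2-column TSV: residue (1..n, contiguous), score."""
    df = pd.read_csv(path, sep="\t")
    if "residue" not in df.columns or "score" not in df.columns:
        raise ValidationError(
            f"accessibility table {path}: expected columns residue, score"
        )
    idx = df["residue"].to_numpy()
    if not np.array_equal(idx, np.arange(1, idx.size + 1)):
        raise ValidationError(
            f"accessibility table {path}: residue column must run 1..n contiguously"
        )
    return AccessibilityProfile(df["score"].to_numpy(dtype=float))


def write_accessibility(profile: AccessibilityProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"residue": np.arange(1, len(profile) + 1), "score": profile.scores}
    ).to_csv(path, sep="\t", index=False)


def truncation_frame(reports: Sequence[TruncationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in reports],
            "first_stop_codon_index": [
                "" if r.first_stop_codon_index is None else r.first_stop_codon_index
                for r in reports
            ],
            "residues_retained": [r.residues_retained for r in reports],
            "residues_lost": [r.residues_lost for r in reports],
            "domains_lost": [";".join(r.domains_lost) for r in reports],
            "domains_disrupted": [";".join(r.domains_disrupted) for r in reports],
        }
    )
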