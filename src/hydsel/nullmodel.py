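"""Monte Carlo null distribution of charge-change class counts.

A genetic selection returns a small batch of mutant clones.  To ask whether
any charge-change class (say, positive -> neutral substitutions) is
overrepresented among the isolated mutations, the selection-free expectation
is simulated: many replicate batches of the same size are drawn from the
error-prone PCR model with no selection applied, each batch's nonsilent
mutations are classified, and the per-class counts across replicates form an
empirical null.  Percentile confidence intervals and add-one upper-tail
empirical p-values are read directly off that null.

The p-value convention is p = (r + 1) / (N + 1), where r is the number of
replicate batches whose class count is at least the observed count.  This is
never zero and is conservative (super-uniform) under the null.  No
multiple-testing correction is applied across the nine classes; the number of
classes is reported alongside each raw p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .eppcr import LibrarySimulator, MutationSpectrum
from .seqcore import (
    CLASS_ORDER,
    CODE_LABELS,
    CODE_NONSENSE,
    CODE_SILENT,
    CODE_STOP_LOSS,
    N_CODES,
    ChargeChangeClass,
    ChargeChangeCounts,
    ChargeScheme,
    CodingSequence,
    ValidationError,
    classify_variant,
    single_mutation_code_table,
)

DEFAULT_N_REPLICATES = 100_000


@dataclass
class NullDistribution:
    """Per-class count distributions over simulated replicate batches.

    ``counts`` is (n_replicates, 12): nine charge-change classes in
    CLASS_ORDER, then nonsense, silent, stop-loss.
    """

    parent_id: str
    batch_size: int
    n_replicates: int
    seed: int
    counts: np.ndarray

    def class_column(self, cls: ChargeChangeClass) -> np.ndarray:
        return self.counts[:, CLASS_ORDER.index(cls)]

    @property
    def expected_mean(self) -> np.ndarray:
        """Mean count per code across replicates (length 12)."""
        return self.counts.mean(axis=0)


def _batch_class_counts(
    sim: LibrarySimulator,
    code_table: np.ndarray,
    scheme: ChargeScheme,
    n_variants: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_variants, 12) classification-code tallies for simulated clones."""
    counts = np.zeros((n_variants, N_CODES), dtype=np.int64)
    if n_variants == 0:
        return counts
    ks, pos, alt = sim.sample_batch_arrays(n_variants, rng)
    if pos.shape[1] == 0:
        return counts
    valid = pos >= 0
    codes = np.zeros_like(pos, dtype=np.int64)
    codes[valid] = code_table[pos[valid], alt[valid]]

    # Clones with two hits in one codon need joint translation: the
    # single-mutation lookup is only valid for isolated substitutions.
    cod = np.where(valid, pos // 3, -np.arange(1, pos.shape[1] + 1)[None, :])
    cod_s = np.sort(cod, axis=1)
    collide = np.flatnonzero((cod_s[:, 1:] == cod_s[:, :-1]).any(axis=1))
    for i in collide:
        k = int(ks[i])
        var = sim.variant_from_row(pos[i], alt[i], k)
        changes = classify_variant(sim.seq, var.mutations, scheme)
        # order within the row is irrelevant for tallying
        codes[i, :k] = [ch.code for ch in changes]

    rows = np.broadcast_to(np.arange(n_variants)[:, None], pos.shape)
    np.add.at(counts, (rows[valid], codes[valid]), 1)
    return counts


def build_null(
    parent: CodingSequence,
    spectrum: MutationSpectrum,
    batch_size: int,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    scheme: Optional[ChargeScheme] = None,
    chunk_replicates: int = 8192,
) -> NullDistribution:
    """Simulate the no-selection null for batches of ``batch_size`` clones.

    Each replicate simulates an entire batch, classifies every mutation
    (silent and nonsense mutations are simulated and tallied, not prevented)
    and records pooled per-class counts.  Deterministic for a given seed.
    """
    if batch_size < 0:
        raise ValidationError("batch_size must be >= 0")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    scheme = scheme or ChargeScheme.default()
    sim = LibrarySimulator(parent, spectrum)
    code_table = single_mutation_code_table(parent, scheme)
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_replicates, N_CODES), dtype=np.int64)
    if batch_size > 0:
        done = 0
        while done < n_replicates:
            reps = min(chunk_replicates, n_replicates - done)
            per_variant = _batch_class_counts(
                sim, code_table, scheme, reps * batch_size, rng
            )
            counts[done : done + reps] = per_variant.reshape(
                reps, batch_size, N_CODES
            ).sum(axis=1)
            done += reps
    return NullDistribution(
        parent_id=parent.id,
        batch_size=batch_size,
        n_replicates=n_replicates,
        seed=seed,
        counts=counts,
    )


def class_ci(
    null: NullDistribution, cls: ChargeChangeClass, level: float = 0.95
) -> tuple[float, float]:
    """Percentile interval of the replicate counts for one class."""
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    col = null.class_column(cls)
    lo, hi = np.quantile(col, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def empirical_p(
    null: NullDistribution, cls: ChargeChangeClass, observed: np.ndarray | int
) -> np.ndarray | float:
    """Add-one upper-tail empirical p for one class; vectorized in observed."""
    col = np.sort(null.class_column(cls))
    obs = np.asarray(observed)
    r = col.size - np.searchsorted(col, obs, side="left")
    p = (r + 1) / (col.size + 1)
    return float(p) if np.isscalar(observed) or obs.ndim == 0 else p


@dataclass
class EnrichmentResult:
    """Observed vs simulated-null summary for one charge-change class."""

    charge_class: ChargeChangeClass
    observed: int
    expected_mean: float
    ci95: tuple[float, float]
    p_value: float
    flagged: bool
    n_replicates: int


def enrichment_test(
    observed: ChargeChangeCounts,
    null: NullDistribution,
    level: float = 0.95,
) -> list[EnrichmentResult]:
    """One-sided (upper tail) empirical enrichment test per charge class.

    A class is flagged when its observed count exceeds the upper bound of the
    null's ``level`` percentile interval.
    """
    if observed.parent_id is not None and observed.parent_id != null.parent_id:
        raise ValidationError(
            f"observed counts are against parent {observed.parent_id!r} but the "
            f"null was built on {null.parent_id!r}"
        )
    results = []
    for cls in CLASS_ORDER:
        obs = observed.classes.get(cls, 0)
        lo, hi = class_ci(null, cls, level)
        results.append(
            EnrichmentResult(
                charge_class=cls,
                observed=obs,
                expected_mean=float(null.class_column(cls).mean()),
                ci95=(lo, hi),
                p_value=empirical_p(null, cls, obs),
                flagged=obs > hi,
                n_replicates=null.n_replicates,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [r.charge_class.label for r in results],
            "observed": [r.observed for r in results],
            "expected_mean": [r.expected_mean for r in results],
            "ci95_lo": [r.ci95[0] for r in results],
            "ci95_hi": [r.ci95[1] for r in results],
            "p_value": [r.p_value for r in results],
            "flagged": [r.flagged for r in results],
        }
    )


def write_report(
    results: Sequence[EnrichmentResult],
    null: NullDistribution,
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write ``<prefix>.json`` and ``<prefix>.tsv`` enrichment reports."""
    prefix = Path(prefix)
    frame = results_to_frame(results)
    tsv = prefix.with_suffix(".tsv")
    frame.to_csv(tsv, sep="\t", index=False)
    doc = {
        "parent_id": null.parent_id,
        "batch_size": null.batch_size,
        "n_replicates": null.n_replicates,
        "seed": null.seed,
        "n_classes_tested": len(results),
        "null_mean_by_code": dict(
            zip(CODE_LABELS, map(float, null.expected_mean))
        ),
        "results": frame.to_dict(orient="records"),
    }
    js = prefix.with_suffix(".json")
    js.write_text(json.dumps(doc, indent=2))
    return js, tsv


def plot_enrichment(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    """Bar plot of observed vs expected counts per class with 95% CI bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [r.charge_class.label for r in results]
    x = np.arange(len(results))
    obs = [r.observed for r in results]
    exp = [r.expected_mean for r in results]
    err = np.array(
        [
            [r.expected_mean - r.ci95[0] for r in results],
            [r.ci95[1] - r.expected_mean for r in results],
        ]
    )
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(x - 0.2, obs, width=0.4, label="observed", color="#c23b22")
    ax.bar(x + 0.2, exp, width=0.4, yerr=err, capsize=3, label="expected (null)",
           color="#4878a8")
    for r, xi in zip(results, x):
        if r.flagged:
            ax.annotate("*", (xi - 0.2, r.observed), ha="center", va="bottom",
                        fontsize=14)
    ax.set_xticks(x, labels, rotation=45, ha="right")
    ax.set_ylabel("mutations per batch")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
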