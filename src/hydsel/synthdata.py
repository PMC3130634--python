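"""Synthetic-data generators for every pipeline input.

The study this pipeline serves deposited no raw sequences, images or tables,
so each analysis stage is exercised on generated data whose statistical
structure matches what the stage assumes:

* a ~574-codon hydrogenase-sized CDS (ATG start, single terminal stop, GC
  controlled);
* selected-variant batches with an optional *planted* excess of one
  charge-change class, emulating what the selection enriched;
* a full mutant summary table (23 variants, 110 nonsilent mutations with a
  fixed lysine-substitution profile and a ladder of truncations) mirroring
  the published per-variant accounting;
* exponential-decay activity series and sigmoid colony-size dose-response
  data;
* plate photographs with ~50 disk-like colonies (via platescan.render_plate);
* accessibility profiles with known surface bumps.

Every generator is a pure function of its parameters and seed; manifests
record both so outputs can be regenerated bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import platescan
from .eppcr import LibrarySimulator, MutationSpectrum
from .fitkit import DoseResponse, TimeCourse, sigmoid
from .seqcore import (
    BASES,
    CODON_TABLE,
    ActivityClass,
    Charge,
    ChargeChangeClass,
    ChargeScheme,
    CodingSequence,
    PointMutation,
    ValidationError,
    VariantRecord,
    classify_mutation,
    single_mutation_code_table,
    CLASS_CODE,
)
from .structmap import AccessibilityProfile, DomainAnnotation

STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Coding sequences
# ---------------------------------------------------------------------------


def generate_cds(
    n_codons: int = 574,
    gc_content: float = 0.5,
    seed: int = 0,
    id: str = "synthetic_cds",
    gc_tolerance: float = 0.02,
    max_attempts: int = 50,
) -> CodingSequence:
    """Generate a CDS: ATG start, terminal stop, no internal stops.

    Bases are drawn with per-base probabilities targeting ``gc_content``;
    internal stop codons are redrawn.  Raises if the realized GC fraction of
    the internal codons (the fixed start and stop codons are not
    controllable) cannot be brought within ``gc_tolerance`` of the target.
    """
    if n_codons < 2:
        raise ValidationError("a CDS needs at least 2 codons (start + stop)")
    if not 0 <= gc_content <= 1:
        raise ValidationError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    for _ in range(max_attempts):
        n_internal = n_codons - 2
        codons = []
        while len(codons) < n_internal:
            draw = rng.choice(4, size=3, p=p)
            codon = "".join(BASES[i] for i in draw)
            if codon not in STOP_CODONS:
                codons.append(codon)
        stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
        nt = "ATG" + "".join(codons) + stop
        internal = "".join(codons)
        gc = (
            (internal.count("G") + internal.count("C")) / len(internal)
            if internal
            else gc_content
        )
        if abs(gc - gc_content) <= gc_tolerance:
            return CodingSequence(id=id, nt=nt, description=f"synthetic CDS gc={gc:.3f}")
    raise ValidationError(
        f"could not reach GC {gc_content:.2f} +/- {gc_tolerance:.2f} in "
        f"{max_attempts} attempts (n_codons={n_codons})"
    )


# ---------------------------------------------------------------------------
# Planted-bias variant batches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedBiasSpec:
    """Enrichment of one charge-change class in generated variant batches.

    ``bias_factor`` multiplies the rate at which target-class mutations occur
    relative to the selection-free error model; 1.0 reproduces the null
    exactly.
    """

    target_class: ChargeChangeClass = ChargeChangeClass(Charge.POS, Charge.NEU)
    bias_factor: float = 1.0
    batch_size: int = 12

    def __post_init__(self) -> None:
        if self.bias_factor < 1:
            raise ValidationError("bias_factor must be >= 1")
        if self.batch_size < 0:
            raise ValidationError("batch_size must be >= 0")


def generate_observed_variants(
    parent: CodingSequence,
    spectrum: MutationSpectrum,
    spec: PlantedBiasSpec,
    seed: int = 0,
    scheme: Optional[ChargeScheme] = None,
) -> list[VariantRecord]:
    """One batch of variants with the target class enriched ``bias_factor``-fold.

    Implemented as exact exponential tilting of the mutation process: under
    the null each clone's mutations form (to truncation) a Poisson process
    over (position, replacement) pairs; tilting by b per target-class
    mutation is equivalent to superposing non-target mutations at their null
    rate with target-class mutations at b times theirs.  The marginal
    distribution of each mutation given its class is untouched, and the
    expected target-class count is exactly bias_factor times the null mean.
    """
    scheme = scheme or ChargeScheme.default()
    sim = LibrarySimulator(parent, spectrum)  # validates spectrum vs parent
    codes = single_mutation_code_table(parent, scheme)
    L = len(parent)
    norm = spectrum.normalized_matrix
    seq_idx = parent.base_index_array()
    # joint law over (position, alt): uniform position x spectrum row
    pair_p = norm[seq_idx] / L  # (L, 4)
    target_code = CLASS_CODE[spec.target_class]
    target_mask = codes == target_code
    q = float(pair_p[target_mask].sum())
    if spec.bias_factor > 1 and q == 0:
        raise ValidationError(
            f"class {spec.target_class.label} is unreachable on parent "
            f"{parent.id!r} under this spectrum"
        )
    lam = spectrum.rate_per_kb * L / 1000.0
    rng = np.random.default_rng(seed)

    def _sampler(mask: np.ndarray):
        flat = np.flatnonzero(mask.ravel())
        w = pair_p.ravel()[flat]
        tot = w.sum()
        if tot == 0:
            return None
        cum = np.cumsum(w / tot)
        cum[-1] = 1.0
        return flat, cum

    t_sampler = _sampler(target_mask)
    nt_sampler = _sampler(~target_mask & (codes != 255))

    variants = []
    for i in range(spec.batch_size):
        while True:
            n_t = rng.poisson(lam * q * spec.bias_factor) if t_sampler else 0
            n_nt = rng.poisson(lam * (1 - q)) if nt_sampler else 0
            if n_t + n_nt > L:
                continue
            picks = []
            for sampler, n in ((t_sampler, n_t), (nt_sampler, n_nt)):
                if n:
                    flat, cum = sampler
                    picks.append(flat[np.searchsorted(cum, rng.random(n))])
            flat_all = np.concatenate(picks) if picks else np.empty(0, dtype=int)
            pos = flat_all // 4
            if np.unique(pos).size == pos.size:
                break
        muts = tuple(
            sorted(
                (
                    PointMutation(
                        position=int(p) + 1,
                        ref_base=BASES[seq_idx[p]],
                        alt_base=BASES[int(f % 4)],
                    )
                    for p, f in zip(pos, flat_all)
                ),
                key=lambda m: m.position,
            )
        )
        variants.append(
            VariantRecord(
                variant_id=f"sim{i + 1:03d}",
                parent_id=parent.id,
                mutations=muts,
                activity_class=ActivityClass.UNKNOWN,
            )
        )
    return variants


# ---------------------------------------------------------------------------
# Kinetics and dose-response
# ---------------------------------------------------------------------------


def generate_decay(
    A0: float = 100.0,
    half_life: float = 8.0,
    times: Sequence[float] = (5, 10, 15, 20, 25),
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[TimeCourse]:
    """Exponential-decay activity series with multiplicative Gaussian noise.

    A(t) = A0 * 2^(-t / half_life), each observation multiplied by
    (1 + noise_cv * eps) and floored at zero.
    """
    if half_life <= 0:
        raise ValidationError("half_life must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    clean = A0 * np.power(2.0, -t / half_life)
    out = []
    for r in range(n_replicates):
        noisy = np.clip(clean * (1 + noise_cv * rng.standard_normal(t.size)), 0, None)
        out.append(TimeCourse(times=t, activities=noisy, replicate_id=f"rep{r + 1}"))
    return out


def generate_dose_response(
    a: float = 120.0,
    b: float = 1.0,
    c: float = 5.2,
    o2_grid: Sequence[float] = (0.0, 2.5, 5.0, 7.5, 10.0, 12.5),
    colonies_per_point: int = 50,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> tuple[DoseResponse, dict[float, np.ndarray]]:
    """Sigmoid colony-size data: per-colony areas log-normal about the curve.

    At each O2 level the mean area follows a / (1 + exp(b (O2 - c))); the
    ``colonies_per_point`` individual areas are log-normal with that mean and
    coefficient of variation ``noise_cv``.  Returns the summary table and the
    per-level colony areas.
    """
    if a <= 0 or colonies_per_point < 1:
        raise ValidationError("plateau and colony count must be positive")
    rng = np.random.default_rng(seed)
    x = np.asarray(o2_grid, dtype=float)
    means, sds, per_point = [], [], {}
    sigma2 = np.log1p(noise_cv**2)
    for o2 in x:
        m = float(sigmoid(o2, a, b, c))
        if noise_cv > 0:
            mu = np.log(m) - sigma2 / 2
            areas = rng.lognormal(mu, np.sqrt(sigma2), size=colonies_per_point)
        else:
            areas = np.full(colonies_per_point, m)
        per_point[float(o2)] = areas
        means.append(areas.mean())
        sds.append(areas.std(ddof=1) if areas.size > 1 else 0.0)
    dr = DoseResponse(
        o2_levels=x,
        responses=np.array(means),
        sd=np.array(sds),
        n=np.full(x.size, colonies_per_point),
    )
    return dr, per_point


# ---------------------------------------------------------------------------
# Accessibility profiles
# ---------------------------------------------------------------------------


def generate_accessibility_profile(
    length: int,
    bumps: Sequence[tuple[int, int, float]] = (),
    baseline: float = 0.2,
    noise: float = 0.05,
    seed: int = 0,
) -> AccessibilityProfile:
    """Uniform-noise baseline plus boxcar bumps (start, end 1-based, amplitude).

    With noise small relative to the bump amplitudes, smoothing and
    mean-thresholding recover the bump intervals (to within the window's
    half-width at the edges).
    """
    rng = np.random.default_rng(seed)
    scores = baseline + rng.uniform(-noise, noise, size=length)
    for start, end, amp in bumps:
        if not 1 <= start <= end <= length:
            raise ValidationError(f"bump ({start}, {end}) outside 1..{length}")
        scores[start - 1 : end] += amp
    return AccessibilityProfile(scores)


# ---------------------------------------------------------------------------
# Emulated mutant summary (per-variant mutation/truncation/activity table)
# ---------------------------------------------------------------------------

#: Illustrative 574-residue architecture: four N-terminal ferredoxin-like
#: domains and a C-terminal catalytic domain (synthetic fixture coordinates).
DEFAULT_DOMAINS: tuple[DomainAnnotation, ...] = (
    DomainAnnotation("FD-like-1", 10, 60),
    DomainAnnotation("FD-like-2", 70, 120),
    DomainAnnotation("FD-like-3", 130, 180),
    DomainAnnotation("FD-like-4", 190, 240),
    DomainAnnotation("catalytic", 260, 560),
)


@dataclass
class MutantSummary:
    """A generated selection outcome: parent CDS, 23 variants, domain map."""

    parent: CodingSequence
    variants: list[VariantRecord]
    domains: tuple[DomainAnnotation, ...]
    manifest: dict


def generate_mutant_summary(seed: int = 0, gc_content: float = 0.42) -> MutantSummary:
    """Emulate the selection's published per-variant accounting.

    The generated table reproduces the study-scale bookkeeping: 23 variants
    (2 fully active, 9 partially active, 12 with no activity) on a
    574-residue parent carrying 110 nonsilent point mutations in total, of
    which 18 alter lysines (4 K->R, 5 K->N, one residue — 390 — hit twice,
    once to isoleucine and once to asparagine), 9 introduce stops forming a
    truncation ladder whose most extreme member retains only 103 residues,
    and the remainder are unconstrained missense changes placed at random.
    """
    rng = np.random.default_rng(seed)
    n_res = 574
    parent = generate_cds(
        n_codons=n_res + 1, gc_content=gc_content, seed=int(rng.integers(2**31)),
        id="hydA_synth",
    )

    # --- plant lysine codons -------------------------------------------------
    # 17 distinct residues carry the 18 lysine substitutions (390 is hit twice)
    special = {390}
    trunc_residues = {104, 150, 200, 250, 300, 400, 500, 493, 542}
    forbidden = special | trunc_residues | {1, n_res + 1}
    pool = [r for r in range(5, n_res - 5) if r not in forbidden]
    k_sites = sorted(
        list(rng.choice(pool, size=16, replace=False).astype(int)) + [390]
    )
    nt = list(parent.nt)
    for r in k_sites:
        nt[(r - 1) * 3 : (r - 1) * 3 + 3] = "AAA"
    for r in trunc_residues:
        nt[(r - 1) * 3 : (r - 1) * 3 + 3] = "CAA"  # Gln; C->T yields TAA stop
    parent = CodingSequence(parent.id, "".join(nt), parent.description)

    # --- planted substitutions ----------------------------------------------
    def k_mut(res: int, kind: str) -> PointMutation:
        base = (res - 1) * 3
        return {
            "R": PointMutation(base + 2, "A", "G"),  # AAA -> AGA (Arg)
            "N": PointMutation(base + 3, "A", "T"),  # AAA -> AAT (Asn)
            "I": PointMutation(base + 2, "A", "T"),  # AAA -> ATA (Ile)
            "E": PointMutation(base + 1, "A", "G"),  # AAA -> GAA (Glu)
            "T": PointMutation(base + 2, "A", "C"),  # AAA -> ACA (Thr)
            "Q": PointMutation(base + 1, "A", "C"),  # AAA -> CAA (Gln)
        }[kind]

    def stop_mut(res: int) -> PointMutation:
        return PointMutation((res - 1) * 3 + 1, "C", "T")  # CAA -> TAA

    other_sites = [r for r in k_sites if r != 390]
    rng.shuffle(other_sites)
    planted: list[tuple[PointMutation, str]] = []  # (mutation, kind tag)
    planted += [(k_mut(r, "R"), "K>R") for r in other_sites[:4]]
    planted += [(k_mut(r, "N"), "K>N") for r in other_sites[4:8]]
    planted.append((k_mut(390, "N"), "K>N"))
    planted.append((k_mut(390, "I"), "K>other"))
    for r, kind in zip(other_sites[8:16], ("E", "T", "Q", "E", "T", "Q", "E", "T")):
        planted.append((k_mut(r, kind), "K>other"))
    assert len(planted) == 18

    # --- variant roles -------------------------------------------------------
    # (id, activity, stop residue or None)
    roles: list[tuple[str, ActivityClass, Optional[int]]] = [
        ("BB01", ActivityClass.FULL, None),
        ("BB02", ActivityClass.FULL, None),
        ("BB03", ActivityClass.PARTIAL, None),
        ("BB04", ActivityClass.PARTIAL, None),
        ("BB05", ActivityClass.PARTIAL, 493),  # lacks 82 residues
        ("BB06", ActivityClass.PARTIAL, None),
        ("BB07", ActivityClass.PARTIAL, None),
        ("BB08", ActivityClass.PARTIAL, None),
        ("BB10", ActivityClass.PARTIAL, None),
        ("BB11", ActivityClass.PARTIAL, None),
        ("BB22", ActivityClass.PARTIAL, 542),  # lacks 33 residues
        ("BB09", ActivityClass.NONE, 150),  # FD-like domains only
        ("BB12", ActivityClass.NONE, 104),  # retains 103 of 574 residues
        ("BB13", ActivityClass.NONE, 200),
        ("BB14", ActivityClass.NONE, 250),
        ("BB15", ActivityClass.NONE, 300),
        ("BB16", ActivityClass.NONE, 400),
        ("BB17", ActivityClass.NONE, 500),
        ("BB18", ActivityClass.NONE, None),
        ("BB19", ActivityClass.NONE, None),
        ("BB20", ActivityClass.NONE, None),
        ("BB21", ActivityClass.NONE, None),
        ("BB23", ActivityClass.NONE, None),
    ]
    n_variants = len(roles)
    per_variant: list[list[PointMutation]] = [[] for _ in range(n_variants)]
    used_residues: list[set[int]] = [set() for _ in range(n_variants)]
    for (vid, _act, stop_res), muts, used in zip(roles, per_variant, used_residues):
        if stop_res is not None:
            muts.append(stop_mut(stop_res))
            used.add(stop_res)

    # spread the 18 lysine changes over distinct variants where possible
    order = rng.permutation(n_variants)
    # residue 390 appears twice: force its two changes into different variants
    planted_390 = [p for p in planted if (p[0].position - 1) // 3 + 1 == 390]
    planted_rest = [p for p in planted if p not in planted_390]
    assignments = list(order[: len(planted_rest)])
    for (mut, _tag), vi in zip(planted_rest, assignments):
        per_variant[vi].append(mut)
        used_residues[vi].add((mut.position - 1) // 3 + 1)
    v390 = [int(order[-1]), int(order[-2])]
    for (mut, _tag), vi in zip(planted_390, v390):
        per_variant[vi].append(mut)
        used_residues[vi].add(390)

    # --- random missense filler ----------------------------------------------
    n_random = 110 - 18 - sum(1 for _, _, s in roles if s is not None)
    # every variant gets at least one mutation before the remainder is spread
    counts = np.zeros(n_variants, dtype=int)
    for vi in range(n_variants):
        if not per_variant[vi]:
            counts[vi] = 1
    remaining = n_random - counts.sum()
    counts += rng.multinomial(remaining, np.full(n_variants, 1 / n_variants))

    k_codons = set(k_sites)
    codes = None  # lazily built after parent edits

    def random_missense(vi: int) -> PointMutation:
        while True:
            res = int(rng.integers(2, n_res + 1))  # exclude start codon and stop
            if res in k_codons or res in trunc_residues or res in used_residues[vi]:
                continue
            codon = parent.codon(res)
            if CODON_TABLE[codon] == "K":
                continue
            options = []
            for offset in range(3):
                for b in BASES:
                    if b == codon[offset]:
                        continue
                    alt = codon[:offset] + b + codon[offset + 1 :]
                    aa = CODON_TABLE[alt]
                    if aa not in ("*", CODON_TABLE[codon]):
                        options.append(
                            PointMutation((res - 1) * 3 + offset + 1, codon[offset], b)
                        )
            if options:
                used_residues[vi].add(res)
                return options[int(rng.integers(len(options)))]

    for vi in range(n_variants):
        for _ in range(int(counts[vi])):
            per_variant[vi].append(random_missense(vi))

    # --- assemble records ----------------------------------------------------
    variants = []
    for (vid, act, stop_res), muts in zip(roles, per_variant):
        if act is ActivityClass.FULL:
            activity = float(rng.uniform(90, 110))
        elif act is ActivityClass.PARTIAL:
            activity = 5.0 if vid == "BB22" else float(rng.uniform(2, 50))
        else:
            activity = 0.0
        variants.append(
            VariantRecord(
                variant_id=vid,
                parent_id=parent.id,
                mutations=tuple(sorted(muts, key=lambda m: m.position)),
                activity_class=act,
                measured_activity=activity,
            )
        )
    manifest = {
        "generator": "generate_mutant_summary",
        "seed": seed,
        "gc_content": gc_content,
        "n_variants": n_variants,
        "n_nonsilent_mutations": sum(len(v.mutations) for v in variants),
        "n_lysine_sites": len(k_sites),
        "truncation_stops": sorted(trunc_residues),
    }
    return MutantSummary(
        parent=parent, variants=variants, domains=DEFAULT_DOMAINS, manifest=manifest
    )


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class GeneratorManifest:
    """Seed, parameters and output checksums for one generator run."""

    generator: str
    seed: int
    parameters: dict
    files: dict[str, str] = field(default_factory=dict)

    def add_file(self, path: str | Path) -> None:
        self.files[str(path)] = file_checksum(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "generator": self.generator,
                    "seed": self.seed,
                    "parameters": self.parameters,
                    "files": self.files,
                },
                indent=2,
                default=str,
            )
        )
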