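"""Synthetic truth sets and caller call sets.

The simulator produces the statistical structure the analysis assumes
without any sequencing data: a truth set of DEL and INS calls with sizes
log-uniform on [50, 10000] bp and inter-variant spacing above 1 kb (the
exclusion rule high-confidence SV benchmarks apply, and the rationale for
the ±500 bp matching window), plus one call set per simulated caller.

Each caller is described by a :class:`CallerProfile`: per-type recall
(every truth call is detected independently with that probability), an
expected Poisson count of false positives placed at least a window plus the
jitter tail away from every truth call, breakpoint jitter drawn from a
discretized double-geometric distribution (heavier-tailed than uniform but
concentrated near zero, matching the small observed neighbor distances),
and dialect quirks the refinement stage must strip: paired start/end
breakend records, sub-50 bp decoy calls, and non-PASS decoy calls.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .records import SVRecord
from .vcfio import write_vcf

__all__ = [
    "SimConfig",
    "CallerProfile",
    "default_profiles",
    "simulate_truth",
    "simulate_caller_calls",
    "simulate_call_sets",
    "write_vcf",
]

_SIZE_RANGE = (50, 10_000)


@dataclass(frozen=True)
class SimConfig:
    """Truth-set generation parameters.

    ``n_truth`` is the number of truth variants per SV type (DEL and INS);
    ``min_spacing`` (default 1001 bp, i.e. strictly more than twice the
    500 bp matching window) keeps every evaluation unambiguous.
    """

    contigs: tuple[tuple[str, int], ...] = (
        ("chr1", 12_000_000),
        ("chr2", 10_000_000),
    )
    n_truth: int = 2000
    size_range: tuple[int, int] = _SIZE_RANGE
    min_spacing: int = 1001
    seed: int = 0

    def __post_init__(self):
        if self.size_range[0] < 50:
            raise ValueError("truth SV sizes must be >= 50 bp")
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be positive")


@dataclass(frozen=True)
class CallerProfile:
    """Statistical profile of one simulated caller."""

    name: str
    recall: Mapping[str, float]
    fp_count: Mapping[str, float]
    jitter_scale: float = 5.0
    emits_paired_records: bool = False
    sub50_fraction: float = 0.0
    nonpass_fraction: float = 0.0
    detects_ins: bool = True

    def __post_init__(self):
        for p in self.recall.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("recall probabilities must be in [0, 1]")
        for frac in (self.sub50_fraction, self.nonpass_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("dialect fractions must be in [0, 1]")


def default_profiles() -> tuple[CallerProfile, ...]:
    """Five caller profiles approximating observed HG002 behaviour.

    DEL recalls follow the measured per-caller values (Manta 0.55,
    DELLY 0.48, GRIDSS 0.42, LUMPY 0.12, SvABA 0.28); INS recall is high
    only for Manta, near zero for DELLY/GRIDSS, and absent for LUMPY and
    SvABA, which do not call insertions at these sizes.  False-positive
    loads are the measured FP counts scaled to a 2000-variant truth set.
    """
    return (
        CallerProfile(
            name="Manta",
            recall={"DEL": 0.55, "INS": 0.19},
            fp_count={"DEL": 344, "INS": 151},
            jitter_scale=4.0,
            sub50_fraction=0.05,
            nonpass_fraction=0.05,
        ),
        CallerProfile(
            name="DELLY",
            recall={"DEL": 0.48, "INS": 0.02},
            fp_count={"DEL": 557, "INS": 5},
            jitter_scale=8.0,
            nonpass_fraction=0.10,
        ),
        CallerProfile(
            name="GRIDSS",
            recall={"DEL": 0.42, "INS": 0.01},
            fp_count={"DEL": 140, "INS": 2},
            jitter_scale=3.0,
            emits_paired_records=True,
            sub50_fraction=0.20,
            nonpass_fraction=0.10,
        ),
        CallerProfile(
            name="LUMPY",
            recall={"DEL": 0.12, "INS": 0.0},
            fp_count={"DEL": 315, "INS": 0},
            jitter_scale=15.0,
            emits_paired_records=True,
            detects_ins=False,
        ),
        CallerProfile(
            name="SvABA",
            recall={"DEL": 0.28, "INS": 0.0},
            fp_count={"DEL": 141, "INS": 0},
            jitter_scale=6.0,
            emits_paired_records=True,
            sub50_fraction=0.05,
            detects_ins=False,
        ),
    )


def _spaced_positions(rng, n: int, low: int, high: int, spacing: int):
    """n sorted positions in [low, high] with pairwise gaps >= spacing.

    Uses the order-statistics construction: uniform draws on the compacted
    interval, sorted, then re-inflated by i*spacing — uniform over all valid
    configurations and O(n log n).
    """
    span = high - low - (n - 1) * spacing
    if n < 0 or span < 0:
        raise ValueError(
            f"cannot place {n} variants with spacing {spacing} in "
            f"[{low}, {high}]"
        )
    if n == 0:
        return np.empty(0, dtype=np.int64)
    base = np.sort(rng.integers(0, span + 1, size=n))
    return low + base + np.arange(n, dtype=np.int64) * spacing


def _log_uniform_sizes(rng, n: int, size_range) -> np.ndarray:
    lo, hi = size_range
    return np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=n)
    ).astype(np.int64).clip(lo, hi)


def simulate_truth(cfg: SimConfig) -> list[SVRecord]:
    """Generate the truth set: ``cfg.n_truth`` DELs and INSs.

    Positions are uniform per contig subject to the spacing constraint
    (DELs and INSs share one spacing pool, as benchmark exclusion rules
    apply across types); counts are allocated to contigs proportionally to
    usable length.  Raises when the genome cannot host the requested count.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    total = 2 * cfg.n_truth
    margin = cfg.size_range[1] + 1
    usable = [max(length - margin, 0) for _, length in cfg.contigs]
    capacity = [u // cfg.min_spacing + 1 if u > 0 else 0 for u in usable]
    if total > sum(capacity):
        raise ValueError(
            f"cannot place {total} truth variants at spacing "
            f"{cfg.min_spacing} on a genome of "
            f"{sum(l for _, l in cfg.contigs)} bp"
        )
    # Largest-remainder allocation proportional to usable length.
    weights = np.array(usable, dtype=float)
    ideal = weights / weights.sum() * total
    alloc = np.floor(ideal).astype(int)
    order = np.argsort(-(ideal - alloc))
    for idx in order:
        if alloc.sum() >= total:
            break
        alloc[idx] += 1
    for i, cap in enumerate(capacity):  # rebalance past capacity
        if alloc[i] > cap:
            excess = alloc[i] - cap
            alloc[i] = cap
            for j in np.argsort(-(np.array(capacity) - alloc)):
                take = min(excess, capacity[j] - alloc[j])
                alloc[j] += take
                excess -= take
                if excess == 0:
                    break

    records: list[SVRecord] = []
    svtypes = np.array(["DEL"] * cfg.n_truth + ["INS"] * cfg.n_truth)
    rng.shuffle(svtypes)
    cursor = 0
    for (name, length), n_here in zip(cfg.contigs, alloc):
        if n_here == 0:
            continue
        pos = _spaced_positions(
            rng, int(n_here), 1, length - margin, cfg.min_spacing
        )
        sizes = _log_uniform_sizes(rng, int(n_here), cfg.size_range)
        for p, size, svtype in zip(
            pos, sizes, svtypes[cursor:cursor + int(n_here)]
        ):
            p, size = int(p), int(size)
            records.append(SVRecord(
                contig=name,
                pos=p,
                svtype=str(svtype),
                end=p + size if svtype == "DEL" else None,
                svlen=size,
                record_id=f"truth_{len(records)}",
            ))
        cursor += int(n_here)
    return records


def _jitter(rng, n: int, scale: float) -> np.ndarray:
    """Discretized double-geometric offsets with mean absolute value
    ``scale``; exactly zero when scale is 0."""
    if scale <= 0 or n == 0:
        return np.zeros(n, dtype=np.int64)
    p = 1.0 / (1.0 + scale)
    magnitude = rng.geometric(p, size=n) - 1
    signs = rng.choice((-1, 1), size=n)
    return (signs * magnitude).astype(np.int64)


def _away_from_truth(rng, n, contigs, truth_by_contig, guard, size_range):
    """Uniform positions at least ``guard`` bp from every truth start."""
    names = [c[0] for c in contigs]
    lengths = np.array([c[1] for c in contigs], dtype=float)
    margin = size_range[1] + 1
    out = []
    attempts = 0
    while len(out) < n and attempts < 200 * max(n, 1):
        attempts += 1
        ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
        name, length = contigs[ci]
        if length <= margin + 1:
            continue
        pos = int(rng.integers(1, length - margin))
        starts = truth_by_contig.get(name)
        if starts is not None and starts.size:
            k = int(np.searchsorted(starts, pos))
            near = min(
                (abs(pos - int(starts[j]))
                 for j in (k - 1, k) if 0 <= j < starts.size),
                default=guard + 1,
            )
            if near <= guard:
                continue
        out.append((name, pos))
    if len(out) < n:
        raise RuntimeError("could not place false positives away from truth")
    return out


def simulate_caller_calls(
    truth: Sequence[SVRecord],
    profile: CallerProfile,
    seed,
    contigs: Sequence[tuple[str, int]],
    size_range: tuple[int, int] = _SIZE_RANGE,
    window: int = 500,
) -> list[SVRecord]:
    """Generate one caller's raw call set from the truth set.

    Truth calls of type T are detected independently with probability
    ``recall[T]`` (insertions are skipped entirely when the profile does
    not call them) at a jittered start; Poisson false positives and the
    dialect decoys (sub-50 bp, non-PASS) are placed far from truth.
    """
    rng = np.random.default_rng(seed)
    guard = window + int(12 * profile.jitter_scale) + 1
    truth_by_contig = {
        name: np.sort(np.array(
            [t.pos for t in truth if t.contig == name], dtype=np.int64))
        for name, _ in contigs
    }
    contig_len = dict(contigs)
    records: list[SVRecord] = []

    detectable = [
        t for t in truth
        if not (t.svtype == "INS" and not profile.detects_ins)
    ]
    probs = np.array([profile.recall.get(t.svtype, 0.0) for t in detectable])
    hits = rng.random(len(detectable)) < probs
    offsets = _jitter(rng, len(detectable), profile.jitter_scale)
    for t, hit, off in zip(detectable, hits, offsets):
        if not hit:
            continue
        size = t.svlen or 0
        pos = int(np.clip(t.pos + off, 1,
                          max(contig_len[t.contig] - size - 1, 1)))
        records.append(SVRecord(
            contig=t.contig,
            pos=pos,
            svtype=t.svtype,
            end=pos + size if t.svtype == "DEL" else None,
            svlen=t.svlen,
            record_id=f"{profile.name}_{len(records)}",
        ))
    n_detected = len(records)

    for svtype in ("DEL", "INS"):
        mean = profile.fp_count.get(svtype, 0.0)
        if svtype == "INS" and not profile.detects_ins:
            mean = 0.0
        n_fp = int(rng.poisson(mean)) if mean > 0 else 0
        sizes = _log_uniform_sizes(rng, n_fp, size_range)
        for (contig, pos), size in zip(
            _away_from_truth(rng, n_fp, contigs, truth_by_contig,
                             guard, size_range),
            sizes,
        ):
            size = int(size)
            records.append(SVRecord(
                contig=contig,
                pos=pos,
                svtype=svtype,
                end=pos + size if svtype == "DEL" else None,
                svlen=size,
                record_id=f"{profile.name}_fp_{len(records)}",
            ))

    n_sub50 = int(rng.binomial(n_detected, profile.sub50_fraction)) \
        if profile.sub50_fraction else 0
    for contig, pos in _away_from_truth(
        rng, n_sub50, contigs, truth_by_contig, guard, size_range
    ):
        size = int(rng.integers(10, 50))
        records.append(SVRecord(
            contig=contig, pos=pos, svtype="DEL", end=pos + size,
            svlen=size, record_id=f"{profile.name}_sub50_{len(records)}",
        ))

    n_nonpass = int(rng.binomial(n_detected, profile.nonpass_fraction)) \
        if profile.nonpass_fraction else 0
    sizes = _log_uniform_sizes(rng, n_nonpass, size_range)
    for (contig, pos), size in zip(
        _away_from_truth(rng, n_nonpass, contigs, truth_by_contig,
                         guard, size_range),
        sizes,
    ):
        size = int(size)
        records.append(SVRecord(
            contig=contig, pos=pos, svtype="DEL", end=pos + size,
            svlen=size, filter=frozenset({"q5"}),
            record_id=f"{profile.name}_lowq_{len(records)}",
        ))

    ckey = {name: i for i, (name, _) in enumerate(contigs)}
    records.sort(key=lambda r: (ckey.get(r.contig, len(ckey)), r.pos,
                                r.record_id or ""))
    return records


def simulate_call_sets(
    cfg: SimConfig,
    profiles: Optional[Sequence[CallerProfile]] = None,
) -> tuple[list[SVRecord], dict[str, list[SVRecord]]]:
    """Generate a truth set plus one call set per profile.

    Per-caller random streams are spawned from the config seed, so adding
    or re-ordering profiles never perturbs the truth set.
    """
    if profiles is None:
        profiles = default_profiles()
    truth = simulate_truth(cfg)
    children = np.random.SeedSequence([cfg.seed, 7919]).spawn(len(profiles))
    call_sets = {
        profile.name: simulate_caller_calls(
            truth, profile, seq, cfg.contigs, cfg.size_range
        )
        for profile, seq in zip(profiles, children)
    }
    return truth, call_sets
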