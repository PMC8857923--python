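"""Synthetic sequence panels with known methylation-driven CpG decay.

The generator is a forward model of the mutational process the CpG_o/e
statistic inverts: genes start as i.i.d. base sequences with a chosen GC
content (expected CpG_o/e = 1), a fraction ``pi_methylated`` of genes is
labelled methylated, and each CpG in a gene is independently lost with the
class decay probability (d_m for methylated, d_u for unmethylated).  A lost
CpG becomes TpG (C→T, the forward-strand deamination footprint) or CpA
(G→A, the reverse-strand footprint) with equal probability, which keeps the
statistic strand-symmetric while producing the TpG enrichment used to
corroborate methylation.  The scan is a single left-to-right pass over the
CpG positions of the input sequence; conversions can never create new CpGs,
so re-eligibility is not an issue.

Ground truth (class labels, conversion counts, pre/post CpG_o/e) is emitted
for every gene so each downstream stage can be checked against what was
planted.  Everything is driven by one seed: identical parameters and seed
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import seqstats
from .seqstats import SequenceRecord

_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass(frozen=True)
class LengthDist:
    """Gene length law: lognormal(mean_log, sd_log) truncated, or uniform."""

    law: str = "lognormal"
    mean_log: float = 7.3
    sd_log: float = 0.4
    min_bp: int = 300
    max_bp: int = 20_000


@dataclass(frozen=True)
class RepeatParams:
    """Repeat-landscape block: genome size, target repeat fraction, families."""

    genome_length: int = 200_000
    repeat_fraction: float = 0.3
    family_count: int = 5
    copies_low: int = 12
    copies_high: int = 40
    element_len_low: int = 80
    element_len_high: int = 400
    divergence: float = 0.05
    decay: float = 0.0
    n_genes: int = 20
    gene_length: int = 1_000
    gene_decay: float = 0.0


@dataclass(frozen=True)
class SimulationParams:
    """One species' generative settings."""

    n_genes: int = 2_000
    length: LengthDist = field(default_factory=LengthDist)
    gc_content: float = 0.4
    pi_methylated: float = 0.5
    decay_methylated: float = 0.5
    decay_unmethylated: float = 0.0
    seed: int = 0
    repeats: RepeatParams | None = None


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.array([_A, _C, _G, _T], dtype=np.uint8)[rng.choice(4, size=n, p=p)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_baseline_gene(
    length: int, gc_content: float, seed: int | np.random.Generator, gene_id: str = "gene"
) -> SequenceRecord:
    """An i.i.d. gene with P(C)=P(G)=gc/2; expected CpG_o/e = 1 asymptotically."""
    if length < 2:
        raise ValueError("length must be >= 2")
    if not (0 < gc_content < 1):
        raise ValueError("gc_content must lie strictly in (0, 1)")
    rng = _rng(seed)
    return SequenceRecord(id=gene_id, seq=_to_str(_random_bases(length, gc_content, rng)),
                          source="simulated")


def _decay_array(arr: np.ndarray, d: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    cpg_pos = np.nonzero((arr[:-1] == _C) & (arr[1:] == _G))[0]
    if len(cpg_pos) == 0 or d == 0:
        return arr, 0
    hit = cpg_pos[rng.random(len(cpg_pos)) < d]
    if len(hit) == 0:
        return arr, 0
    out = arr.copy()
    c_side = rng.random(len(hit)) < 0.5
    out[hit[c_side]] = _T          # CpG -> TpG
    out[hit[~c_side] + 1] = _A     # CpG -> CpA
    return out, int(len(hit))


def apply_methylation_decay(
    seq: str, d: float, seed: int | np.random.Generator
) -> tuple[str, int]:
    """Convert each CpG independently with probability d; return (seq, conversions).

    Each conversion rewrites exactly one base: C→T (TpG footprint) or G→A
    (CpA footprint), chosen with probability 1/2 each, so the Hamming
    distance to the input equals the conversion count.
    """
    if not (0 <= d <= 1):
        raise ValueError("decay probability must be in [0, 1]")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out, n = _decay_array(arr, d, _rng(seed))
    return _to_str(out), n


def _draw_lengths(n: int, dist: LengthDist, rng: np.random.Generator) -> np.ndarray:
    if dist.law == "uniform":
        return rng.integers(dist.min_bp, dist.max_bp + 1, size=n)
    if dist.law == "lognormal":
        raw = rng.lognormal(dist.mean_log, dist.sd_log, size=n)
        return np.clip(raw, dist.min_bp, dist.max_bp).astype(int)
    raise ValueError(f"unknown length law {dist.law!r}")


def simulate_species(
    params: SimulationParams, species: str = "sim"
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate one species' gene set plus its ground-truth table.

    Truth columns: gene_id, methylated, decay_applied (conversion count),
    pre_decay_cpg_oe, post_decay_cpg_oe, length.  The expected class-mean
    post/pre CpG_o/e ratio is ≈ (1 − d), slightly above because conversions
    also deplete C (or G), shrinking the expectation's denominator.
    """
    rng = _rng(params.seed)
    lengths = _draw_lengths(params.n_genes, params.length, rng)
    methylated = rng.random(params.n_genes) < params.pi_methylated
    records: list[SequenceRecord] = []
    rows = []
    for i in range(params.n_genes):
        gid = f"{species}_g{i:05d}"
        base = _random_bases(int(lengths[i]), params.gc_content, rng)
        d = params.decay_methylated if methylated[i] else params.decay_unmethylated
        decayed, n_conv = _decay_array(base, d, rng)
        pre = seqstats.compute_cpg_oe(seqstats._count_array(base))
        post = seqstats.compute_cpg_oe(seqstats._count_array(decayed))
        records.append(SequenceRecord(id=gid, seq=_to_str(decayed), source="simulated"))
        rows.append(
            {
                "gene_id": gid,
                "methylated": bool(methylated[i]),
                "decay_applied": n_conv,
                "pre_decay_cpg_oe": pre,
                "post_decay_cpg_oe": post,
                "length": int(lengths[i]),
            }
        )
    return records, pd.DataFrame(rows)


def simulate_repeat_landscape(
    params: RepeatParams, gc_content: float = 0.4, seed: int | np.random.Generator = 0
) -> tuple[dict[str, str], list[tuple[str, int, int, str]], list[tuple[str, int, int, str]], pd.DataFrame]:
    """Assemble a genome of background, planted genes, and repeat families.

    Each family is a master sequence copied with per-copy substitution
    divergence and CpG decay at the family decay rate.  Copy counts are
    rescaled so realized repeat coverage lands within ±0.02 of the target
    fraction.  Returns (genome, repeat intervals, gene intervals, truth).
    """
    rng = _rng(seed)
    if not (0 <= params.repeat_fraction <= 0.9):
        raise ValueError("repeat_fraction must be in [0, 0.9]")
    G = params.genome_length
    target = params.repeat_fraction * G

    families = []
    if params.family_count > 0 and target > 0:
        lens = rng.integers(params.element_len_low, params.element_len_high + 1,
                            size=params.family_count)
        copies = rng.integers(params.copies_low, params.copies_high + 1,
                              size=params.family_count)
        total = float(np.sum(lens * copies))
        scale = target / total
        copies = np.maximum(1, np.round(copies * scale).astype(int))
        for f in range(params.family_count):
            master = _random_bases(int(lens[f]), gc_content, rng)
            families.append((f"fam{f:03d}", master, int(copies[f])))

    segments: list[tuple[str, np.ndarray]] = []  # (label, bases)
    for fam_id, master, n_copies in families:
        for _ in range(n_copies):
            copy = master.copy()
            sub = rng.random(len(copy)) < params.divergence
            if sub.any():
                copy[sub] = _random_bases(int(sub.sum()), gc_content, rng)[: sub.sum()]
            copy, _ = _decay_array(copy, params.decay, rng)
            segments.append((fam_id, copy))
    for g in range(params.n_genes):
        gene = _random_bases(params.gene_length, gc_content, rng)
        gene, _ = _decay_array(gene, params.gene_decay, rng)
        segments.append((f"gene{g:04d}", gene))

    placed = sum(len(s) for _, s in segments)
    if placed > 0.95 * G:
        raise ValueError(
            f"cannot pack {placed} bp of repeats+genes into a {G} bp genome"
        )
    # distribute remaining background around the shuffled segments
    n_gaps = len(segments) + 1
    background = G - placed
    cuts = np.sort(rng.integers(0, background + 1, size=n_gaps - 1))
    gap_lens = np.diff(np.concatenate([[0], cuts, [background]]))
    order = rng.permutation(len(segments))

    parts: list[np.ndarray] = []
    repeat_iv: list[tuple[str, int, int, str]] = []
    gene_iv: list[tuple[str, int, int, str]] = []
    pos = 0
    contig = "chr1"
    for slot, seg_idx in enumerate(order):
        gap = _random_bases(int(gap_lens[slot]), gc_content, rng)
        parts.append(gap)
        pos += len(gap)
        label, bases = segments[seg_idx]
        start, end = pos, pos + len(bases)
        (gene_iv if label.startswith("gene") else repeat_iv).append(
            (contig, start, end, label)
        )
        parts.append(bases)
        pos = end
    parts.append(_random_bases(int(gap_lens[-1]), gc_content, rng))
    genome = {contig: _to_str(np.concatenate(parts) if parts else np.array([], dtype=np.uint8))}

    truth = pd.DataFrame(
        {
            "family_id": [f for f, _, _ in families],
            "element_len": [len(m) for _, m, _ in families],
            "n_copies": [c for _, _, c in families],
        }
    )
    return genome, sorted(repeat_iv, key=lambda iv: iv[1]), sorted(gene_iv, key=lambda iv: iv[1]), truth


@dataclass
class PanelSim:
    """A simulated multi-species panel with its planted orthology."""

    records: dict[str, list[SequenceRecord]]
    truths: dict[str, pd.DataFrame]
    partition: dict[str, dict[str, list[str]]]
    complete_orthogroups: list[str]


def simulate_panel(
    species_params: Sequence[tuple[str, SimulationParams]],
    shared_fraction: float = 0.3,
    complete_fraction: float = 1.0,
    bias: float = 1.0,
    seed: int = 0,
) -> PanelSim:
    """Simulate a species panel and tag genes into cross-species orthogroups.

    ``shared_fraction`` of the smallest species' gene count becomes
    orthogroups; a ``complete_fraction`` of those contain every species (the
    rest drop one random species, so n-way recovery has negatives to reject).
    Within each species, each orthogroup member is drawn from the methylated
    (low CpG_o/e) gene pool with probability ``bias``, otherwise uniformly —
    bias 1 plants the conserved-genes-are-methylated association, bias 0
    plants independence.
    """
    if len(species_params) < 2:
        raise ValueError("need >= 2 species for a panel")
    rng = np.random.default_rng(seed)
    records: dict[str, list[SequenceRecord]] = {}
    truths: dict[str, pd.DataFrame] = {}
    pools: dict[str, dict[str, list[str]]] = {}
    for name, params in species_params:
        params = replace(params, seed=int(rng.integers(0, 2**31)))
        recs, truth = simulate_species(params, species=name)
        records[name] = recs
        truths[name] = truth
        meth = truth.loc[truth["methylated"], "gene_id"].tolist()
        rest = truth.loc[~truth["methylated"], "gene_id"].tolist()
        rng.shuffle(meth)
        rng.shuffle(rest)
        pools[name] = {"methylated": meth, "unmethylated": rest}

    n_og = int(round(shared_fraction * min(len(r) for r in records.values())))
    species_names = [name for name, _ in species_params]
    partition: dict[str, dict[str, list[str]]] = {}
    complete: list[str] = []
    for i in range(n_og):
        og = f"OG{i:07d}"
        members = list(species_names)
        is_complete = rng.random() < complete_fraction
        if not is_complete:
            members.remove(species_names[int(rng.integers(len(members)))])
        group: dict[str, list[str]] = {sp: [] for sp in species_names}
        ok = True
        for sp in members:
            pool = pools[sp]
            use_meth = rng.random() < bias
            source = pool["methylated"] if use_meth else None
            if source is None:
                # unbiased: uniform over all remaining genes
                n_m, n_u = len(pool["methylated"]), len(pool["unmethylated"])
                if n_m + n_u == 0:
                    ok = False
                    break
                source = pool["methylated"] if rng.random() < n_m / (n_m + n_u) else pool["unmethylated"]
            if not source:
                source = pool["unmethylated"] or pool["methylated"]
            if not source:
                ok = False
                break
            group[sp] = [source.pop()]
        if not ok:
            break
        partition[og] = group
        if is_complete:
            complete.append(og)
    return PanelSim(records=records, truths=truths, partition=partition,
                    complete_orthogroups=complete)
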