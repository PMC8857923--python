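"""Per-gene CpG and TpG observed/expected ratios from sequence.

CpG sites are lost over evolutionary time where germline cytosines are
methylated, because methyl-C deaminates to T at a high rate.  The depletion
statistic computed here, CpG_o/e = P_CpG / (P_C * P_G), is therefore a
sequence-only proxy for historical gene body methylation: values well below 1
indicate a methylated history, values near 1 an unmethylated one.  TpG_o/e is
the corroborating footprint (the product of CpG deamination on the forward
strand is TpG).

Conventions
-----------
* P_CpG = N_CpG / W_eff where W_eff counts overlapping dinucleotide windows
  whose two bases are both unambiguous; P_C = N_C / L_eff and
  P_G = N_G / L_eff where L_eff counts unambiguous bases.
* Non-ACGT symbols (IUPAC ambiguity codes, N) are masked: excluded from
  L_eff, from any window they touch, and from all counts.  U is read as T.
* Ratios are undefined (None, with a recorded reason) when a required count
  is zero; they are never silently coerced to 0.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_A, _C, _G, _T, _U = (ord(b) for b in "ACGTU")

#: Genes shorter than this many bp are excluded from all downstream analyses.
DEFAULT_MIN_LEN = 300
#: CpG_o/e above this is retained but flagged; modality/clustering drop it.
DEFAULT_CEILING = 2.0

EXCLUSION_NONE = "none"
EXCLUSION_TOO_SHORT = "too_short"
EXCLUSION_ZERO_C_OR_G = "zero_c_or_g"
EXCLUSION_NO_WINDOWS = "no_windows"


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: id, uppercased sequence, and provenance."""

    id: str
    seq: str
    source: str = ""


@dataclass(frozen=True)
class DinucleotideCounts:
    """Mono- and dinucleotide tallies over the unambiguous part of a sequence."""

    l_eff: int
    w_eff: int
    n_a: int
    n_c: int
    n_g: int
    n_t: int
    n_cpg: int
    n_tpg: int


@dataclass(frozen=True)
class GeneStat:
    """CpG_o/e and TpG_o/e of one gene plus its filter status."""

    id: str
    length_raw: int
    cpg_oe: float | None
    tpg_oe: float | None
    passed_filter: bool
    exclusion_reason: str
    flagged_high: bool = False


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into SequenceRecords.

    Sequences are uppercased and U is normalised to T.  The id is the header
    token before the first whitespace.  Duplicate ids raise; an empty file
    returns an empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(id=rec.id, seq=seq, source=f"{path}:{i}"))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write SequenceRecords as plain FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for j in range(0, len(rec.seq), width):
                fh.write(rec.seq[j : j + width] + "\n")


def _seq_to_array(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    arr[arr == _U] = _T
    return arr


def count_dinucleotides(seq: str) -> DinucleotideCounts:
    """Tally unambiguous bases and overlapping dinucleotide windows.

    Windows containing any non-ACGT symbol contribute to neither W_eff nor
    the dinucleotide counts; non-ACGT bases contribute to neither L_eff nor
    the mononucleotide counts.
    """
    if not seq:
        raise ValueError("empty sequence")
    return _count_array(_seq_to_array(seq))


def _count_array(arr: np.ndarray) -> DinucleotideCounts:
    is_a = arr == _A
    is_c = arr == _C
    is_g = arr == _G
    is_t = arr == _T
    valid = is_a | is_c | is_g | is_t
    l_eff = int(valid.sum())
    if arr.size >= 2:
        w_eff = int((valid[:-1] & valid[1:]).sum())
        n_cpg = int((is_c[:-1] & is_g[1:]).sum())
        n_tpg = int((is_t[:-1] & is_g[1:]).sum())
    else:
        w_eff = n_cpg = n_tpg = 0
    return DinucleotideCounts(
        l_eff=l_eff,
        w_eff=w_eff,
        n_a=int(is_a.sum()),
        n_c=int(is_c.sum()),
        n_g=int(is_g.sum()),
        n_t=int(is_t.sum()),
        n_cpg=n_cpg,
        n_tpg=n_tpg,
    )


def compute_cpg_oe(counts: DinucleotideCounts) -> float | None:
    """CpG_o/e = (N_CpG/W_eff) / ((N_C/L_eff)*(N_G/L_eff)); None if undefined."""
    if counts.n_c == 0 or counts.n_g == 0 or counts.w_eff == 0:
        return None
    p_cpg = counts.n_cpg / counts.w_eff
    p_c = counts.n_c / counts.l_eff
    p_g = counts.n_g / counts.l_eff
    return p_cpg / (p_c * p_g)


def compute_tpg_oe(counts: DinucleotideCounts) -> float | None:
    """TpG_o/e computed the same way, with N_T in place of N_C."""
    if counts.n_t == 0 or counts.n_g == 0 or counts.w_eff == 0:
        return None
    p_tpg = counts.n_tpg / counts.w_eff
    p_t = counts.n_t / counts.l_eff
    p_g = counts.n_g / counts.l_eff
    return p_tpg / (p_t * p_g)


def gene_stat(
    record: SequenceRecord,
    min_len: int = DEFAULT_MIN_LEN,
    ceiling: float = DEFAULT_CEILING,
) -> GeneStat:
    """Score one gene; genes under min_len bp or with undefined CpG_o/e fail the filter."""
    length = len(record.seq)
    if length < min_len:
        return GeneStat(record.id, length, None, None, False, EXCLUSION_TOO_SHORT)
    counts = count_dinucleotides(record.seq)
    cpg = compute_cpg_oe(counts)
    tpg = compute_tpg_oe(counts)
    if cpg is None:
        reason = EXCLUSION_NO_WINDOWS if counts.w_eff == 0 else EXCLUSION_ZERO_C_OR_G
        return GeneStat(record.id, length, None, tpg, False, reason)
    return GeneStat(
        record.id,
        length,
        cpg,
        tpg,
        True,
        EXCLUSION_NONE,
        flagged_high=cpg > ceiling,
    )


def profile_species(
    records: Sequence[SequenceRecord],
    min_len: int = DEFAULT_MIN_LEN,
    ceiling: float = DEFAULT_CEILING,
) -> list[GeneStat]:
    """Score every gene of a species, preserving input order.

    Raises if no gene survives the filters (the inputs are unusable for any
    downstream statistic).  Logs the per-reason attrition.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    stats = [gene_stat(rec, min_len=min_len, ceiling=ceiling) for rec in records]
    reasons = Counter(s.exclusion_reason for s in stats if not s.passed_filter)
    n_pass = sum(s.passed_filter for s in stats)
    logger.info(
        "profiled %d genes: %d passed, exclusions=%s", len(stats), n_pass, dict(reasons)
    )
    if stats and n_pass == 0:
        raise ValueError(
            f"all {len(stats)} genes excluded ({dict(reasons)}); inputs unusable"
        )
    return stats


def stats_to_frame(stats: Sequence[GeneStat]) -> pd.DataFrame:
    """GeneStats as a DataFrame, one row per gene, input order preserved."""
    return pd.DataFrame(
        {
            "id": [s.id for s in stats],
            "length": [s.length_raw for s in stats],
            "cpg_oe": [s.cpg_oe for s in stats],
            "tpg_oe": [s.tpg_oe for s in stats],
            "passed_filter": [s.passed_filter for s in stats],
            "exclusion_reason": [s.exclusion_reason for s in stats],
        }
    )


def write_stats_tsv(stats: Sequence[GeneStat], path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False)


def read_stats_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "cpg_oe", "passed_filter"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stats table {path} lacks columns {sorted(missing)}")
    return df


def passing_values(stats: Sequence[GeneStat]) -> np.ndarray:
    """CpG_o/e values of genes that passed the filter (defined values only)."""
    return np.array(
        [s.cpg_oe for s in stats if s.passed_filter and s.cpg_oe is not None],
        dtype=float,
    )
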