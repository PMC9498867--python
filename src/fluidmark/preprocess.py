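"""Raw-read cleaning: adapter location, UMI extraction, QC accounting.

A raw read is kept only if its mean base quality is acceptable, a 3'
adapter can be located (prefix match with bounded mismatches), the insert
in front of the UMI falls inside the 18-30 nt size-selection window, and
the insert does not end in a poly-A run.  Every discard is tallied under a
reason so that raw = clean + sum(discards) holds exactly per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator


class CleanRead(NamedTuple):
    sample_id: str
    insert: str
    umi: str


@dataclass
class PreprocessConfig:
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    umi_length: int = 10
    max_mismatch: int = 1
    min_overlap: int = 8
    min_insert: int = 18
    max_insert: int = 30
    polya_min: int = 8          # trailing A run that triggers the poly-A rule
    min_mean_quality: float = 20.0
    five_prime_adapter: str | None = None  # optional 5' contaminant screen

    def __post_init__(self) -> None:
        if len(self.adapter) < self.min_overlap:
            raise ValueError("adapter shorter than min_overlap")
        if self.min_insert < 1 or self.max_insert < self.min_insert:
            raise ValueError("invalid insert window")


@dataclass
class QCStats:
    """Per-sample cleaning statistics (Q20 and read accounting)."""

    sample_id: str
    raw_reads: int = 0
    clean_reads: int = 0
    q20_fraction: float = 0.0
    discard_reasons: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.clean_reads + sum(self.discard_reasons.values()) != self.raw_reads:
            raise ValueError(f"{self.sample_id}: read accounting does not balance")
        if not 0.0 <= self.q20_fraction <= 1.0:
            raise ValueError(f"{self.sample_id}: q20_fraction outside [0, 1]")


class FastqParseError(ValueError):
    pass


def _mismatches_le(a: str, b: str, limit: int) -> bool:
    """True if Hamming distance between equal-length strings <= limit."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def locate_adapter(
    read: str,
    adapter: str,
    max_mismatch: int = 1,
    min_overlap: int = 8,
    min_pos: int = 0,
) -> int | None:
    """Leftmost position where the read suffix matches an adapter prefix.

    The adapter prefix of length ``min(len(adapter), len(read) - p)`` must
    overlap by at least ``min_overlap`` bases and differ by at most
    ``max_mismatch`` substitutions.  Returns ``None`` if no position at or
    beyond ``min_pos`` qualifies.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(read)
    alen = len(adapter)
    last = n - min_overlap  # last admissible start position
    if last < min_pos:
        return None
    # exact full-adapter hit bounds the scan; mismatched hits can only be
    # to its left, so correctness vs a brute-force scan is preserved.
    exact = read.find(adapter, min_pos) if alen <= n - min_pos else -1
    stop = exact if exact != -1 else last + 1
    if max_mismatch > 0 or exact == -1:
        for p in range(min_pos, min(stop, last + 1)):
            if _mismatches_le(read[p:p + alen], adapter[: n - p], max_mismatch):
                return p
    return exact if exact != -1 else None


def clean_sample(fastq_path, cfg: PreprocessConfig,
                 sample_id: str | None = None) -> tuple[list[CleanRead], QCStats]:
    """Clean one FASTQ file into (insert, UMI) pairs with QC accounting.

    Discard reasons: ``low_quality`` (mean Phred below threshold),
    ``five_prime_contaminant`` (optional screen), ``no_adapter``, ``short``
    (insert below the window), ``long`` (above it), ``polya`` (insert ends
    in a run of >= ``polya_min`` A).  ``q20_fraction`` is the fraction of
    retained-read bases with Phred >= 20.
    """
    sample = sample_id or _stem(fastq_path)
    stats = QCStats(sample_id=sample)
    reads: list[CleanRead] = []
    discard = stats.discard_reasons
    q20_char = chr(33 + 20)
    q20_bases = 0
    total_bases = 0
    polya_tail = "A" * cfg.polya_min
    fpa = cfg.five_prime_adapter

    def drop(reason: str) -> None:
        discard[reason] = discard.get(reason, 0) + 1

    # cache per unique quality string: (mean phred, #bases >= Q20)
    qual_cache: dict[str, tuple[float, int]] = {}

    with open(fastq_path) as fh:
        iterator = FastqGeneralIterator(fh)
        idx = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqParseError(
                    f"{fastq_path}: malformed FASTQ record #{idx}: {exc}"
                ) from exc
            idx += 1
            stats.raw_reads += 1
            cached = qual_cache.get(qual)
            if cached is None:
                mean_q = sum(map(ord, qual)) / len(qual) - 33 if qual else 0.0
                nq20 = sum(1 for c in qual if c >= q20_char)
                cached = (mean_q, nq20)
                qual_cache[qual] = cached
            mean_q, nq20 = cached
            if mean_q < cfg.min_mean_quality:
                drop("low_quality")
                continue
            if fpa and seq.startswith(fpa):
                drop("five_prime_contaminant")
                continue
            p = locate_adapter(seq, cfg.adapter, cfg.max_mismatch,
                               cfg.min_overlap, min_pos=cfg.umi_length)
            if p is None:
                drop("no_adapter")
                continue
            insert = seq[: p - cfg.umi_length]
            umi = seq[p - cfg.umi_length: p]
            if len(insert) < cfg.min_insert:
                drop("short")
                continue
            if len(insert) > cfg.max_insert:
                drop("long")
                continue
            if insert.endswith(polya_tail):
                drop("polya")
                continue
            reads.append(CleanRead(sample, insert, umi))
            stats.clean_reads += 1
            q20_bases += nq20
            total_bases += len(qual)

    stats.q20_fraction = q20_bases / total_bases if total_bases else 0.0
    stats.validate()
    return reads, stats


def _stem(path) -> str:
    from pathlib import Path

    return Path(path).stem
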