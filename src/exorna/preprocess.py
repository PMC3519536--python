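"""Read cleanup with full accounting: 3' adapter trimming, then removal of
adapter-only, too-short/too-long, polyA-only and low-quality reads.

The library is sequenced single-end into the 3' adapter, so a read is
``insert + adapter(+ noise)``; trimming truncates at the leftmost position
where an adapter prefix of length >= ``min_overlap`` aligns with a mismatch
fraction <= ``max_adapter_mismatch_rate``.  Rejection reasons are applied in
a fixed precedence (adapter_only, too_short, too_long, polyA_only,
low_quality) so summaries are deterministic, and counts always conserve:
kept + rejected = input.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, DataError
from .reads import Read, VALID_BASES

REJECT_REASONS = ("adapter_only", "too_short", "too_long", "polyA_only", "low_quality")


@dataclass
class PreprocessParams:
    adapter_3p: str
    min_overlap: int = 5
    max_adapter_mismatch_rate: float = 0.1
    min_length: int = 16
    max_length: int = 35
    min_mean_quality: float = 20.0
    polyA_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not self.adapter_3p:
            raise ConfigError("adapter sequence must be non-empty")
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")
        if self.min_length > self.max_length:
            raise ConfigError("min_length must be <= max_length")
        if not 0.0 <= self.max_adapter_mismatch_rate <= 1.0:
            raise ConfigError("max_adapter_mismatch_rate must lie in [0, 1]")
        if not 0.0 <= self.polyA_fraction <= 1.0:
            raise ConfigError("polyA_fraction must lie in [0, 1]")


@dataclass
class PreprocessSummary:
    input_count: int = 0
    kept_count: int = 0
    rejections: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REJECT_REASONS}
    )

    def check(self) -> None:
        if self.kept_count + sum(self.rejections.values()) != self.input_count:
            raise AssertionError("preprocess accounting violated")

    def as_dict(self) -> dict:
        return {
            "input": self.input_count,
            "kept": self.kept_count,
            **{f"rejected_{k}": v for k, v in self.rejections.items()},
        }


def _mismatch(a: str, b: str) -> bool:
    # N never matches, itself included
    return a != b or a == "N" or b == "N"


def trim_adapter(read: Read, params: PreprocessParams) -> tuple[Read, bool]:
    """Truncate at the leftmost adapter alignment; returns (read, trimmed?).

    A position t matches when some adapter prefix of length
    o in [min_overlap, min(len - t, len(adapter))] aligns at t with
    mismatches/o <= max_adapter_mismatch_rate.  No match leaves the read
    unchanged; a match at t = 0 yields an empty (adapter-only) read.
    """
    seq = read.seq.upper()
    adapter = params.adapter_3p.upper()
    n, alen = len(seq), len(adapter)
    rate = params.max_adapter_mismatch_rate
    for t in range(0, n - params.min_overlap + 1):
        max_o = min(n - t, alen)
        mism = 0
        matched = False
        for o in range(1, max_o + 1):
            if _mismatch(seq[t + o - 1], adapter[o - 1]):
                mism += 1
            if o >= params.min_overlap and mism <= rate * o:
                matched = True
                break
        if matched:
            return (
                Read(read.read_id, read.seq[:t], read.quality[:t] if read.quality else None),
                True,
            )
    return read, False


def _reject_reason(read: Read, was_trimmed: bool, params: PreprocessParams) -> str | None:
    n = len(read.seq)
    if was_trimmed and n == 0:
        return "adapter_only"
    if n < params.min_length:
        return "too_short"
    if n > params.max_length:
        return "too_long"
    if n > 0 and read.seq.upper().count("A") / n >= params.polyA_fraction:
        return "polyA_only"
    mq = read.mean_quality()
    if mq is not None and mq < params.min_mean_quality:
        return "low_quality"
    return None


def filter_reads(
    reads: list[Read] | tuple[Read, ...], params: PreprocessParams
) -> tuple[list[Read], PreprocessSummary]:
    """Trim every read, reject by the fixed precedence, conserve counts.

    Reads without quality strings (FASTA input) pass the quality filter.
    Non-ACGTN characters raise a data error naming the read.
    """
    summary = PreprocessSummary()
    kept: list[Read] = []
    for read in reads:
        bad = set(read.seq) - VALID_BASES
        if bad:
            raise DataError(
                f"read {read.read_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        summary.input_count += 1
        trimmed, was_trimmed = trim_adapter(read, params)
        reason = _reject_reason(trimmed, was_trimmed, params)
        if reason is None:
            kept.append(trimmed)
            summary.kept_count += 1
        else:
            summary.rejections[reason] += 1
    summary.check()
    return kept, summary
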