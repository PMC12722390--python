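"""Reporter sub-transcript selection and per-cell UMI quantification.

Fluorescent reporter transgenes (tdTomato = "red", EGFP = "green") share
locally similar stretches at the nucleotide level, so reads falling in those
stretches cannot be attributed to one reporter.  This module selects
*sub-transcripts*: maximal segments of each reporter whose windowed identity
to the other reporter, under a global pairwise alignment, stays strictly
below a threshold (default 20%).  Per-cell reporter expression is then the
sum of deduplicated UMIs incident on each marker's sub-transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "ReporterSequence",
    "SubTranscript",
    "select_subtranscripts",
    "quantify_reporter_umis",
    "cross_identity",
]

_VALID = set("ACGT")


@dataclass(frozen=True)
class ReporterSequence:
    """A reporter coding sequence; ``marker_id`` is ``"red"`` or ``"green"``."""

    marker_id: str
    sequence: str

    def __post_init__(self) -> None:
        if self.marker_id not in ("red", "green"):
            raise ValueError("marker_id must be 'red' or 'green'")
        if not self.sequence:
            raise ValueError("empty reporter sequence")
        bad = set(self.sequence.upper()) - _VALID
        if bad:
            raise ValueError(f"invalid nucleotides in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SubTranscript:
    """A low-cross-identity segment [start, end) of a parent reporter."""

    marker_id: str
    start: int
    end: int
    max_cross_identity: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def _aligner(local: bool = False) -> Align.PairwiseAligner:
    # EMBOSS-style DNA scores.  Gap extension must be much cheaper than a
    # mismatch, otherwise the aligner pairs unrelated stretches base-to-base
    # (~25% spurious identity) instead of leaving them unaligned, and no
    # window ever drops below a 20% identity threshold.
    a = Align.PairwiseAligner()
    a.mode = "local" if local else "global"
    a.match_score = 5.0
    a.mismatch_score = -4.0
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    return a


def _match_profiles(seq_a: str, seq_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position match indicators for both sequences under one global
    alignment.  A position matches when the alignment pairs it with an
    identical base; positions opposite gaps or mismatches score 0."""
    aln = _aligner().align(seq_a.upper(), seq_b.upper())[0]
    idx = aln.indices  # (2, ncols); -1 where a sequence is gapped
    arr_a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    arr_b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    match_a = np.zeros(len(seq_a), dtype=float)
    match_b = np.zeros(len(seq_b), dtype=float)
    both = (idx[0] >= 0) & (idx[1] >= 0)
    ia, ib = idx[0][both], idx[1][both]
    eq = arr_a[ia] == arr_b[ib]
    match_a[ia[eq]] = 1.0
    match_b[ib[eq]] = 1.0
    return match_a, match_b


def _windowed_identity(match: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling identity (matches / window, gaps count as mismatch).

    Ends inherit the nearest full window's value so every position gets a
    profile entry.
    """
    n = len(match)
    if n < window:
        return np.full(n, match.mean())
    kernel = np.ones(window) / window
    valid = np.convolve(match, kernel, mode="valid")  # length n - window + 1
    out = np.empty(n)
    half = (window - 1) // 2
    out[half : half + len(valid)] = valid
    out[:half] = valid[0]
    out[half + len(valid):] = valid[-1]
    return out


def cross_identity(seq: str, other: str, start: int, end: int) -> float:
    """Cross-reporter identity of ``seq[start:end]``: the fraction of the
    segment's positions that pair with an identical base in the global
    alignment of the two full reporters.

    The check is anchored to the full-length alignment on purpose: an
    *optimal* re-alignment of an isolated segment against the other reporter
    always fishes ~25%+ spurious identity out of unrelated DNA, so no
    segment could ever pass a 20% bound under it.
    """
    match, _ = _match_profiles(seq, other)
    return float(match[start:end].mean())


def _segments_below(
    profile: np.ndarray, threshold: float, min_length: int
) -> list[tuple[int, int]]:
    """Maximal runs where profile < threshold, trimmed of short runs."""
    below = profile < threshold
    segs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(list(below) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_length:
                segs.append((start, i))
            start = None
    return segs


def select_subtranscripts(
    red: ReporterSequence,
    green: ReporterSequence,
    identity_threshold: float = 0.20,
    window: int = 30,
    min_length: int = 30,
) -> dict[str, list[SubTranscript]]:
    """Select low-identity sub-transcripts for both reporters.

    The two sequences are globally aligned once; each sequence's windowed
    identity profile is thresholded and the maximal runs strictly below
    ``identity_threshold`` become candidate segments.  Candidates shorter
    than ``min_length`` are discarded, and every returned segment is
    re-verified against its unwindowed matched fraction under the same
    alignment (see :func:`cross_identity`).
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")
    if min_length < 1 or window < min_length:
        raise ValueError("require window >= min_length >= 1")

    match_red, match_green = _match_profiles(red.sequence, green.sequence)
    out: dict[str, list[SubTranscript]] = {"red": [], "green": []}
    for marker, match in (("red", match_red), ("green", match_green)):
        profile = _windowed_identity(match, window)
        k = 0
        for start, end in _segments_below(profile, identity_threshold, min_length):
            ident = float(match[start:end].mean())
            if ident < identity_threshold:
                k += 1
                out[marker].append(
                    SubTranscript(
                        marker_id=marker,
                        start=start,
                        end=end,
                        max_cross_identity=ident,
                        name=f"{marker}_sub{k}",
                    )
                )
    return out


def quantify_reporter_umis(
    assignments: pd.DataFrame,
    subtranscripts: dict[str, str] | list[SubTranscript],
) -> pd.DataFrame:
    """Per-cell reporter expression as summed deduplicated UMIs.

    ``assignments`` has columns (barcode, umi, subtranscript_id); rows may
    repeat (PCR duplicates).  Within each sub-transcript, UMIs are
    deduplicated by the (umi, subtranscript_id) key, then counts are summed
    across each marker's sub-transcripts ("algebraic sum of incident UMIs").
    ``subtranscripts`` maps sub-transcript id to marker id, or is a list of
    named :class:`SubTranscript` objects.

    Returns a DataFrame indexed by barcode with ``red_umis``/``green_umis``.
    """
    if isinstance(subtranscripts, dict):
        sub_to_marker = dict(subtranscripts)
    else:
        sub_to_marker = {st.name: st.marker_id for st in subtranscripts}
        if len(sub_to_marker) != len(subtranscripts):
            raise ValueError("subtranscript names must be unique")

    required = {"barcode", "umi", "subtranscript_id"}
    missing = required - set(assignments.columns)
    if missing:
        raise ValueError(f"assignments table missing columns: {sorted(missing)}")

    if len(assignments):
        unknown = set(assignments["subtranscript_id"]) - set(sub_to_marker)
        if unknown:
            raise ValueError(
                f"unknown subtranscript_id in assignments: {sorted(unknown)}"
            )
        dedup = assignments.drop_duplicates(
            subset=["barcode", "umi", "subtranscript_id"]
        ).copy()
        dedup["marker"] = dedup["subtranscript_id"].map(sub_to_marker)
        counts = (
            dedup.groupby(["barcode", "marker"], sort=True)
            .size()
            .unstack(fill_value=0)
        )
    else:
        counts = pd.DataFrame(columns=["red", "green"])
    for marker in ("red", "green"):
        if marker not in counts.columns:
            counts[marker] = 0
    out = counts[["red", "green"]].rename(
        columns={"red": "red_umis", "green": "green_umis"}
    )
    out.index.name = "barcode"
    return out.astype(int)
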