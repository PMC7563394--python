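"""Variant-centered conservation windows and the motif presence test.

A fixed-width window (default 100 nt, variant in the middle) is cut from
the mRNA-sense 3'UTR around each variant; windows are written as FASTA for
external motif discovery.  Given a motif (a plain consensus string, or one
extracted from a MEME text file), its presence across a 3'UTR set is tested
with a two-sided Fisher exact test: a transcript counts as "present" when
the motif or its reverse complement occurs at least once.  Presence — not
the occurrence count — enters the test; occurrence totals are reported
descriptively.

The 2x2 table compares the foreground presence ratio against either
(a) a control transcript set ("control" mode, the default), or
(b) the expected presence count under an i.i.d. nucleotide background model
    built from the tested set's own base composition ("iid" mode).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_formats import UTRSequence, VariantRecord, reverse_complement


@dataclass(frozen=True)
class ConservationWindow:
    """A variant-centered substring of an mRNA-sense 3'UTR."""

    variant: VariantRecord
    transcript_id: str
    width: int
    sequence: str
    offset_of_variant: int  # 1-based within the window

    def __post_init__(self):
        if len(self.sequence) > self.width:
            raise ValueError("window longer than requested width")
        if not 1 <= self.offset_of_variant <= len(self.sequence):
            raise ValueError("variant offset outside window")


@dataclass(frozen=True)
class MotifTestResult:
    """Motif presence counts over a 3'UTR set plus the Fisher exact p-value."""

    motif: str
    n_present: int
    n_total: int
    expected_present: float
    p_value: float
    occurrence_count: int
    mode: str = "control"

    def __post_init__(self):
        if not 0 <= self.n_present <= self.n_total:
            raise ValueError("need 0 <= n_present <= n_total")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def extract_window(utr: UTRSequence, v: VariantRecord, width: int = 100
                   ) -> ConservationWindow:
    """Cut a width-nt window from the UTR with the variant in the middle.

    For even width the variant sits at offset ``width/2`` (width/2 bases up
    to and including the variant, width/2 after); odd widths are symmetric.
    Windows are clipped at the UTR boundaries, with the variant offset
    adjusted accordingly.
    """
    if width < 1:
        raise ValueError("width must be positive")
    offset = utr.genomic_to_offset(v.pos)
    if offset is None:
        raise ValueError(f"variant {v.chrom}:{v.pos} outside UTR "
                         f"{utr.transcript_id}")
    left = (width - 1) // 2
    right = width - 1 - left
    start = max(1, offset - left)
    end = min(len(utr), offset + right)
    return ConservationWindow(
        variant=v, transcript_id=utr.transcript_id, width=width,
        sequence=utr.sequence[start - 1:end],
        offset_of_variant=offset - start + 1,
    )


def write_windows_fasta(windows: Sequence[ConservationWindow],
                        path: str | Path) -> None:
    """Write windows as FASTA, one record per variant, ready for MEME runs."""
    records = []
    for w in windows:
        v = w.variant
        rid = f"{w.transcript_id}_{v.chrom}_{v.pos}_{v.ref}_{v.alt}"
        desc = f"variant_offset={w.offset_of_variant} width={w.width}"
        records.append(SeqRecord(Seq(w.sequence), id=rid, description=desc))
    SeqIO.write(records, str(path), "fasta")


def count_motif(motif: str, utrs: Sequence[UTRSequence]
                ) -> tuple[int, int, int]:
    """Count motif presence and occurrences over a 3'UTR set.

    Returns ``(n_present, occurrence_count, n_total)``.  A transcript is
    "present" when the motif or its reverse complement occurs at least
    once; occurrences are counted at every start offset in both
    orientations (overlaps allowed), a palindromic motif once per offset.
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("empty motif")
    if not set(motif) <= set("ACGT"):
        raise ValueError(f"motif must be DNA (ACGT), got {motif!r}")
    rc = reverse_complement(motif)
    needles = (motif,) if motif == rc else (motif, rc)  # palindrome once
    n_present = 0
    occurrences = 0
    for u in utrs:
        seq = u.sequence
        hits = 0
        for needle in needles:
            i = seq.find(needle)
            while i != -1:
                hits += 1
                i = seq.find(needle, i + 1)
        occurrences += hits
        if hits:
            n_present += 1
    return n_present, occurrences, len(utrs)


def iid_presence_expectation(motif: str, utrs: Sequence[UTRSequence]) -> float:
    """Expected number of motif-present transcripts under an i.i.d. model.

    The background uses the set's pooled base composition; the per-offset
    hit probability covers the motif and its reverse complement, and the
    per-transcript presence probability is ``1 - (1 - p_offset)^n_offsets``.
    """
    motif = motif.upper()
    rc = reverse_complement(motif)
    pooled = "".join(u.sequence for u in utrs)
    total = len(pooled)
    if total == 0:
        return 0.0
    freq = {b: pooled.count(b) / total for b in "ACGT"}
    p_fwd = math.prod(freq.get(b, 0.0) for b in motif)
    p_off = p_fwd if motif == rc else p_fwd + math.prod(
        freq.get(b, 0.0) for b in rc)
    expected = 0.0
    for u in utrs:
        n_offsets = max(0, len(u) - len(motif) + 1)
        expected += 1.0 - (1.0 - p_off) ** n_offsets
    return expected


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table.
    Integer arithmetic makes the tie comparison exact.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    if n == 0:
        return 1.0
    # weight(k) = C(row1, k) * C(row2, col1 - k); p(k) = weight(k)/C(n, col1).
    # Walk the support with the exact integer recurrence
    #   w(k+1) * (k+1) * (row2 - col1 + k + 1) = w(k) * (row1 - k) * (col1 - k)
    # (the division is exact), so ties are compared in integer arithmetic.
    k_min = max(0, col1 - row2)
    k_max = min(col1, row1)
    w = math.comb(row1, k_min) * math.comb(row2, col1 - k_min)
    weights = {}
    total = 0
    for k in range(k_min, k_max + 1):
        weights[k] = w
        total += w
        if k < k_max:
            w = (w * (row1 - k) * (col1 - k)) \
                // ((k + 1) * (row2 - col1 + k + 1))
    w_obs = weights[a]
    tail = sum(wk for wk in weights.values() if wk <= w_obs)
    return tail / total


def fisher_presence_test(n_present: int, n_total: int,
                         background: tuple[int, int] | float,
                         motif: str = "", occurrence_count: int = 0
                         ) -> MotifTestResult:
    """Fisher exact test of a presence ratio against a background.

    ``background`` is either ``(bg_present, bg_total)`` counts from a
    control transcript set (mode "control"), or an expected presence count
    for ``n_total`` transcripts from an analytic background model (mode
    "iid"; rounded to the nearest integer to form the table).
    """
    if n_present > n_total:
        raise ValueError("n_present exceeds n_total")
    if isinstance(background, tuple):
        bg_present, bg_total = background
        if bg_present > bg_total:
            raise ValueError("background present count exceeds its total")
        expected = (bg_present * n_total / bg_total) if bg_total else 0.0
        table = (n_present, n_total - n_present,
                 bg_present, bg_total - bg_present)
        mode = "control"
    else:
        expected = float(background)
        exp_int = int(round(expected))
        exp_int = min(max(exp_int, 0), n_total)
        table = (n_present, n_total - n_present, exp_int, n_total - exp_int)
        mode = "iid"
    p = fisher_exact_two_sided(*table)
    return MotifTestResult(motif=motif, n_present=n_present, n_total=n_total,
                           expected_present=expected, p_value=p,
                           occurrence_count=occurrence_count, mode=mode)


def motif_presence_test(motif: str, utrs: Sequence[UTRSequence],
                        background: Sequence[UTRSequence] | None = None
                        ) -> MotifTestResult:
    """Count a motif over a 3'UTR set and run the Fisher presence test.

    With a ``background`` transcript set the test compares the two observed
    presence ratios ("control" mode); without one it falls back to the
    i.i.d. composition model ("iid" mode).
    """
    n_present, occ, n_total = count_motif(motif, utrs)
    if background is not None:
        bg_present, _, bg_total = count_motif(motif, background)
        bg: tuple[int, int] | float = (bg_present, bg_total)
    else:
        bg = iid_presence_expectation(motif, utrs)
    return fisher_presence_test(n_present, n_total, bg, motif=motif.upper(),
                                occurrence_count=occ)


def read_meme_consensus(path: str | Path) -> list[str]:
    """Extract consensus strings from a MEME text-format motif file.

    The consensus takes the highest-probability base per column of each
    letter-probability matrix (ties broken alphabetically).
    """
    text = Path(path).read_text()
    motifs: list[str] = []
    blocks = re.split(r"^MOTIF\s+", text, flags=re.M)[1:]
    for block in blocks:
        m = re.search(
            r"letter-probability matrix:[^\n]*\n((?:\s*[\d.eE+-]+[^\n]*\n)+)",
            block)
        if not m:
            continue
        consensus = []
        for line in m.group(1).strip().splitlines():
            probs = [float(x) for x in line.split()]
            if len(probs) < 4:
                raise ValueError(f"bad letter-probability row in {path}: "
                                 f"{line!r}")
            best = max(range(4), key=lambda i: (probs[i], -i))
            consensus.append("ACGT"[best])
        motifs.append("".join(consensus))
    if not motifs:
        raise ValueError(f"no MEME motifs found in {path}")
    return motifs
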