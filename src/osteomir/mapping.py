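"""Cross-platform signature mapping by exact k-mer sequence homology.

Prognostic miRNA profiles defined on one assay (e.g. DASL microarray probes)
are carried to another platform (small-RNA-seq or TaqMan panels) by requiring
a perfect contiguous match of at least ``k`` bases (default 18) between the
probe sequence and a mature miRNA reference sequence.  U/T and case
differences are canonicalized away before matching; matches may start at any
offset in either sequence.  Probes matching more than one reference are
reported against every match and flagged ambiguous rather than silently
assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

_ALLOWED = set("ACGTU")


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A mature miRNA (or probe) sequence; U and T are equivalent."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _ALLOWED
        if bad:
            raise SequenceError(f"{self.id}: illegal characters {sorted(bad)}")

    @property
    def canonical(self) -> str:
        """Upper-case DNA alphabet (U -> T)."""
        return self.sequence.upper().replace("U", "T")


@dataclass
class SignatureDefinition:
    """A named profile given as probe sequences plus its intended miRNAs."""

    name: str
    probes: list[SequenceRecord]
    intended_features: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ProbeMatch:
    probe_id: str
    feature_id: str
    probe_offset: int
    ref_offset: int
    length: int
    ambiguous: bool


def read_fasta(path) -> list[SequenceRecord]:
    """Read miRBase-style FASTA into sequence records."""
    return [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _best_match(probe: str, ref: str, k: int) -> tuple[int, int, int] | None:
    """Longest exact shared run of length >= k; leftmost in the probe on ties.

    Returns (probe_offset, ref_offset, length) or None.  Runs a window scan:
    every k-mer of the probe is located in the reference and extended
    maximally in both directions.
    """
    best: tuple[int, int, int] | None = None
    for i in range(len(probe) - k + 1):
        kmer = probe[i : i + k]
        start = 0
        while True:
            j = ref.find(kmer, start)
            if j < 0:
                break
            pi, rj = i, j
            while pi > 0 and rj > 0 and probe[pi - 1] == ref[rj - 1]:
                pi -= 1
                rj -= 1
            length = k
            while (
                pi + length < len(probe)
                and rj + length < len(ref)
                and probe[pi + length] == ref[rj + length]
            ):
                length += 1
            if best is None or length > best[2] or (length == best[2] and pi < best[0]):
                best = (pi, rj, length)
            start = j + 1
    return best


def map_signature(
    sig: SignatureDefinition,
    references: list[SequenceRecord],
    k: int = 18,
) -> pd.DataFrame:
    """Map every probe of a signature onto reference sequences.

    Returns one row per (probe, matched reference) with the match offset in
    both sequences and the matched length; probes without any >=k exact run
    get a single row with an empty feature id.  A probe hitting several
    references is flagged ambiguous on every one of its rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    short = [p.id for p in sig.probes if len(p.sequence) < k]
    if short:
        raise SequenceError(f"probe(s) shorter than k={k}: {short}")
    rows = []
    for probe in sig.probes:
        pseq = probe.canonical
        hits = []
        for ref in references:
            match = _best_match(pseq, ref.canonical, k)
            if match is not None:
                hits.append((ref.id, *match))
        if not hits:
            rows.append((probe.id, "", -1, -1, 0, False))
            continue
        ambiguous = len(hits) > 1
        for feature_id, poff, roff, length in hits:
            rows.append((probe.id, feature_id, poff, roff, length, ambiguous))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "feature_id", "probe_offset", "ref_offset", "length", "ambiguous"],
    )


def mapped_features(mapping: pd.DataFrame) -> list[str]:
    """Unambiguously mapped feature ids, in probe order."""
    ok = mapping[(mapping["feature_id"] != "") & (~mapping["ambiguous"])]
    seen: list[str] = []
    for fid in ok["feature_id"]:
        if fid not in seen:
            seen.append(fid)
    return seen
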