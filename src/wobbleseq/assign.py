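"""Modification-aware read assignment, pileups and QC.

Reads in this protocol are 3' suffixes of mature tRNA references (the reverse
transcriptase starts at the 3'CCA and either reaches the 5' end or stops at a
modified site), so scoring is 3'-anchored: a read of length l is compared
against the terminal l bases of each candidate reference and scored by its
number of *non-exempt* mismatches.  Mismatches at annotated modification
sites -- including the wobble position of ANN families, where inosine is read
as G -- are exempt when ``mod_site_free`` is set, so the modification signal
itself never penalises assignment.

A single terminal indel is tolerated through shifted re-comparison (cost 1);
internal indels are not scored.  Ties within one anticodon family receive
equal fractional weights; ties across families are dropped as ambiguous.
Pileups accumulate only from assigned reads.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import NUCS, ReferenceSet

_CODE = {c: i for i, c in enumerate(NUCS)}

UNIQUE, FRACTIONAL, AMBIGUOUS, UNASSIGNED = (
    "unique",
    "fractional",
    "ambiguous_cross_family",
    "unassigned",
)


@dataclass
class AssignParams:
    max_mismatch: int = 3
    mod_site_free: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass
class PositionPileup:
    """Per-isodecoder, per-position base counts (A,C,G,T) plus the count of
    reads whose 5' end (truncation start) falls at each position."""

    base_counts: dict[str, np.ndarray] = field(default_factory=dict)  # L x 4
    trunc_starts: dict[str, np.ndarray] = field(default_factory=dict)  # L

    @classmethod
    def empty(cls, refset: ReferenceSet) -> "PositionPileup":
        return cls(
            base_counts={
                i: np.zeros((len(r.sequence), 4)) for i, r in refset.records.items()
            },
            trunc_starts={
                i: np.zeros(len(r.sequence)) for i, r in refset.records.items()
            },
        )

    def add(self, other: "PositionPileup") -> "PositionPileup":
        for iso, arr in other.base_counts.items():
            self.base_counts.setdefault(iso, np.zeros_like(arr))
            self.base_counts[iso] += arr
            self.trunc_starts.setdefault(iso, np.zeros_like(other.trunc_starts[iso]))
            self.trunc_starts[iso] += other.trunc_starts[iso]
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iso in sorted(self.base_counts):
            bc = self.base_counts[iso]
            ts = self.trunc_starts[iso]
            for pos in range(bc.shape[0]):
                rows.append((iso, pos, *bc[pos].tolist(), ts[pos]))
        return pd.DataFrame(
            rows, columns=["id", "pos", "A", "C", "G", "T", "trunc"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PositionPileup":
        pile = cls()
        for iso, grp in df.groupby("id", sort=True):
            grp = grp.sort_values("pos")
            pile.base_counts[str(iso)] = grp[["A", "C", "G", "T"]].to_numpy(float)
            pile.trunc_starts[str(iso)] = grp["trunc"].to_numpy(float)
        return pile


@dataclass
class AssignmentResult:
    """Per-read outcomes plus the resulting (fractional) count vectors."""

    outcomes: list[tuple[str, tuple]]  # (category, payload)
    counts: pd.Series  # per isodecoder, fractional
    anticodon_counts: pd.Series  # per family label
    n_reads: int
    n_unique: int
    n_fractional: int
    n_ambiguous: int
    n_unassigned: int
    full_length_flags: np.ndarray  # per assigned read: start == 0
    cca_flags: np.ndarray  # per full-length assigned read: ends with CCA
    nuclear_flags: np.ndarray  # per assigned read: best reference nuclear

    @property
    def n_assigned(self) -> int:
        return self.n_unique + self.n_fractional


def read_fastq(path: str | Path):
    """Yield (name, sequence) from a plain or gzipped FASTQ file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTQ not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record in {path}: {header!r}")
            yield header[1:].strip().split()[0], seq


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().replace("U", "T").encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


class _RefIndex:
    """Encoded references with per-suffix exemption masks."""

    def __init__(self, refset: ReferenceSet, params: AssignParams) -> None:
        if len(refset) == 0:
            raise ValueError("empty reference")
        self.refset = refset
        self.ids = sorted(refset.records)
        self.codes = [_encode(refset.records[i].sequence) for i in self.ids]
        self.lengths = np.array([len(c) for c in self.codes])
        self.families = [refset.records[i].family_key for i in self.ids]
        self.nuclear = np.array(
            [refset.records[i].genome == "nuclear" for i in self.ids]
        )
        self.exempt: list[np.ndarray] = []
        for i in self.ids:
            rec = refset.records[i]
            mask = np.zeros(len(rec.sequence), dtype=bool)
            if params.mod_site_free:
                for pos, _ in rec.mod_sites:
                    mask[pos] = True
                if rec.is_ann:
                    mask[rec.wobble_index] = True
            self.exempt.append(mask)

    def suffix_matrices(self, length: int):
        """Stacked suffix codes and exemption masks for refs of len >= length."""
        keep = np.flatnonzero(self.lengths >= length)
        if keep.size == 0:
            return keep, None, None
        codes = np.stack([self.codes[k][-length:] for k in keep])
        exempt = np.stack([self.exempt[k][-length:] for k in keep])
        return keep, codes, exempt


def _score_block(
    reads: np.ndarray, codes: np.ndarray, exempt: np.ndarray
) -> np.ndarray:
    """Non-exempt mismatch counts: reads (N x l) vs refs (R x l) -> N x R."""
    mism = reads[:, None, :] != codes[None, :, :]
    mism &= ~exempt[None, :, :]
    return mism.sum(axis=2)


def assign_reads(
    fastq,
    refset: ReferenceSet,
    params: AssignParams | None = None,
) -> tuple[AssignmentResult, PositionPileup]:
    """Assign reads to isodecoders and accumulate per-position pileups.

    *fastq* is a path (plain or .gz) or an iterable of (name, sequence).
    Scores every read against every reference whose length can contain it
    (3'-anchored); the minimum non-exempt mismatch count wins if it does not
    exceed ``max_mismatch``.  If no reference qualifies, a single terminal
    indel (read or reference trimmed by one base at the 3' end, cost 1) is
    tried before declaring the read unassigned.
    """
    params = params or AssignParams()
    index = _RefIndex(refset, params)

    if isinstance(fastq, (str, Path)):
        reads = list(read_fastq(fastq))
    else:
        reads = list(fastq)

    outcomes: list[tuple[str, tuple]] = [None] * len(reads)  # type: ignore
    counts = pd.Series(0.0, index=index.ids)
    pile = PositionPileup.empty(refset)
    n_unique = n_frac = n_amb = n_unassigned = 0
    full_length: list[bool] = []
    cca: list[bool] = []
    nuclear: list[bool] = []

    by_len: dict[int, list[int]] = {}
    encoded = []
    for ri, (_, seq) in enumerate(reads):
        code = _encode(seq)
        encoded.append(code)
        by_len.setdefault(len(code), []).append(ri)

    CHUNK = 2048
    for length, idxs in sorted(by_len.items()):
        if length == 0:
            for ri in idxs:
                outcomes[ri] = (UNASSIGNED, ())
                n_unassigned += 1
            continue
        keep, codes, exempt = index.suffix_matrices(length)
        for lo in range(0, len(idxs), CHUNK):
            chunk = idxs[lo : lo + CHUNK]
            if keep.size:
                block = np.stack([encoded[ri] for ri in chunk])
                scores = _score_block(block, codes, exempt)
            else:
                scores = np.full((len(chunk), 0), np.iinfo(np.int64).max)
            for row, ri in enumerate(chunk):
                sc = scores[row]
                best = int(sc.min()) if sc.size else np.iinfo(np.int64).max
                tied = keep[np.flatnonzero(sc == best)] if sc.size else np.array([], int)
                if best > params.max_mismatch:
                    shifted = _indel_rescue(encoded[ri], index, params)
                    if shifted is None:
                        outcomes[ri] = (UNASSIGNED, ())
                        n_unassigned += 1
                        continue
                    best, tied = shifted
                fams = {index.families[t] for t in tied}
                if len(fams) > 1:
                    outcomes[ri] = (AMBIGUOUS, tuple(index.ids[t] for t in tied))
                    n_amb += 1
                    continue
                w = 1.0 / len(tied)
                payload = tuple((index.ids[t], w) for t in tied)
                if len(tied) == 1:
                    outcomes[ri] = (UNIQUE, payload)
                    n_unique += 1
                else:
                    outcomes[ri] = (FRACTIONAL, payload)
                    n_frac += 1
                read_code = encoded[ri]
                for t in tied:
                    iso = index.ids[t]
                    counts[iso] += w
                    start = index.lengths[t] - len(read_code)
                    _accumulate(pile, iso, read_code, int(start), w)
                t0 = tied[0]
                start0 = int(index.lengths[t0] - len(read_code))
                fl = start0 == 0
                full_length.append(fl)
                nuclear.append(bool(index.nuclear[t0]))
                if fl:
                    tail = read_code[-3:]
                    cca.append(
                        len(tail) == 3
                        and tail[0] == _CODE["C"]
                        and tail[1] == _CODE["C"]
                        and tail[2] == _CODE["A"]
                    )

    fam_counts: dict[str, float] = {}
    for iso, c in counts.items():
        fam_counts.setdefault(refset.family_of(iso).label, 0.0)
        fam_counts[refset.family_of(iso).label] += c
    result = AssignmentResult(
        outcomes=outcomes,
        counts=counts,
        anticodon_counts=pd.Series(fam_counts).sort_index(),
        n_reads=len(reads),
        n_unique=n_unique,
        n_fractional=n_frac,
        n_ambiguous=n_amb,
        n_unassigned=n_unassigned,
        full_length_flags=np.array(full_length, dtype=bool),
        cca_flags=np.array(cca, dtype=bool),
        nuclear_flags=np.array(nuclear, dtype=bool),
    )
    return result, pile


def _indel_rescue(read_code: np.ndarray, index: _RefIndex, params: AssignParams):
    """Retry with one terminal indel (cost 1).  Returns (score, tied) or None."""
    best = params.max_mismatch + 1
    tied: list[int] = []
    variants = []
    if len(read_code) > 1:
        variants.append((read_code[:-1], 0))  # extra base at read 3' end
    variants.append((read_code, 1))  # missing base: compare vs ref[:-1] suffix
    for code, trim_ref in variants:
        l = len(code)
        for t in range(len(index.ids)):
            ref = index.codes[t][:-1] if trim_ref else index.codes[t]
            ex = index.exempt[t][:-1] if trim_ref else index.exempt[t]
            if len(ref) < l:
                continue
            mism = (code != ref[-l:]) & ~ex[-l:]
            score = int(mism.sum()) + 1
            if score < best:
                best, tied = score, [t]
            elif score == best:
                tied.append(t)
    if best > params.max_mismatch or not tied:
        return None
    return best, np.array(sorted(set(tied)), dtype=int)


def _accumulate(
    pile: PositionPileup, iso: str, read_code: np.ndarray, start: int, w: float
) -> None:
    bc = pile.base_counts[iso]
    L = bc.shape[0]
    # clip defensively: indel-rescued reads may overhang by one base
    usable = read_code[max(0, len(read_code) - (L - start)) :]
    positions = np.arange(L - len(usable), L)
    valid = usable >= 0
    np.add.at(bc, (positions[valid], usable[valid]), w)
    pile.trunc_starts[iso][positions[0] if len(positions) else start] += w


@dataclass
class QCReport:
    unique_fraction: float
    nuclear_mapped_fraction: float
    full_length_fraction: float
    cca_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def qc_metrics(assignment: AssignmentResult) -> QCReport:
    """Library QC: unique fraction of all reads, nuclear-mapped fraction of
    assigned reads, full-length fraction of assigned reads (5' end reaches
    position 0), and the CCA-tail fraction among full-length reads."""
    total = max(assignment.n_reads, 1)
    assigned = max(assignment.n_assigned, 1)
    n_fl = int(assignment.full_length_flags.sum())
    return QCReport(
        unique_fraction=assignment.n_unique / total,
        nuclear_mapped_fraction=float(assignment.nuclear_flags.sum()) / assigned,
        full_length_fraction=n_fl / assigned,
        cca_fraction=float(assignment.cca_flags.sum()) / max(n_fl, 1),
    )


def write_counts(
    counts: pd.DataFrame, anticodon_counts: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write isodecoder- and anticodon-level count matrices as TSV (full
    precision, fractional counts preserved)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iso_path = out_dir / "counts_isodecoder.tsv"
    fam_path = out_dir / "counts_anticodon.tsv"
    counts.to_csv(iso_path, sep="\t", index_label="id")
    anticodon_counts.to_csv(fam_path, sep="\t", index_label="family")
    return iso_path, fam_path


def stack_replicates(
    results: dict[str, AssignmentResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-replicate assignment results into isodecoder x replicate
    and family x replicate count matrices."""
    iso = pd.DataFrame({col: r.counts for col, r in results.items()}).fillna(0.0)
    fam = pd.DataFrame({col: r.anticodon_counts for col, r in results.items()}).fillna(0.0)
    return iso, fam
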