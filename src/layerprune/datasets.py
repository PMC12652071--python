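"""Variant-centred DNA classification datasets.

This module generates, reads and writes the tabular datasets the rest of
the toolkit consumes: fixed-length DNA windows centred on a
single-nucleotide variant, each carrying a binary pathogenic/benign label.
The synthetic generator plants a short causal motif near the centre of
pathogenic sequences (and rejection-samples it out of benign ones), so the
label is perfectly predictable from sequence content and a small encoder
can learn the task at desk scale. The real eQTL causal-variant benchmark
is reachable through :func:`load_benchmark_split` when its hosting
libraries and network are available.

The native on-disk format is a CSV with the exact header
``id,sequence,label``; FASTA export writes a sidecar two-column TSV of
labels so both files stay greppable.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    GenerationError,
    InvalidArgumentError,
    ParseError,
    ResourceError,
    UnknownSplitError,
)

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"
_BASES = np.array(list("ACGT"))

#: Hugging Face accession of the eQTL causal-variant benchmark.
BENCHMARK_ACCESSION = "InstaDeepAI/genomics-long-range-benchmark"
BENCHMARK_TASK = "variant_effect_causal_eqtl"
BENCHMARK_SPLITS = ("train", "test")


@dataclass(frozen=True)
class VariantRecord:
    """One variant-centred sequence with its binary label.

    ``label`` is 1 for pathogenic/causal, 0 for benign/non-causal.
    """

    id: str
    sequence: str
    label: int


@dataclass(frozen=True)
class DatasetSplit:
    """An ordered collection of equal-length records forming one split."""

    name: str
    records: tuple[VariantRecord, ...]
    L: int

    def __post_init__(self):
        ids = set()
        for i, rec in enumerate(self.records):
            if len(rec.sequence) != self.L:
                raise InvalidArgumentError(
                    f"record {rec.id!r} (index {i}) has length "
                    f"{len(rec.sequence)}, split declares L={self.L}"
                )
            if not set(rec.sequence) <= set(ALPHABET):
                bad = sorted(set(rec.sequence) - set(ALPHABET))
                raise InvalidArgumentError(
                    f"record {rec.id!r} contains non-alphabet characters {bad}"
                )
            if rec.label not in (0, 1):
                raise InvalidArgumentError(
                    f"record {rec.id!r} has label {rec.label!r}, expected 0 or 1"
                )
            if rec.id in ids:
                raise InvalidArgumentError(f"duplicate record id {rec.id!r}")
            ids.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def class_counts(self) -> tuple[int, int]:
        """Return ``(n_benign, n_pathogenic)``; they sum to ``len(self)``."""
        labels = self.labels
        return int(np.sum(labels == 0)), int(np.sum(labels == 1))

    def digest(self) -> str:
        """Content hash (id, sequence, label, order) for provenance."""
        h = hashlib.sha256()
        h.update(f"{self.name}:{self.L}\n".encode())
        for rec in self.records:
            h.update(f"{rec.id}\t{rec.sequence}\t{rec.label}\n".encode())
        return h.hexdigest()


@dataclass(frozen=True)
class MotifModel:
    """Signal structure of the synthetic benchmark.

    A fixed ``causal_motif`` is planted in pathogenic sequences with its
    centre within ``placement_window`` positions of the sequence centre
    (0-based index ``L // 2``); benign sequences are rejection-sampled
    until they contain no occurrence of the motif anywhere. The default
    window of 2 keeps the planted 6-mer overlapping the central variant
    position itself, mirroring how a causal single-nucleotide variant
    creates or disrupts a binding motif at its own locus. ``decoy_motifs``
    are planted in records of both classes at uniform random positions and
    carry no label information. ``label_noise`` flips that fraction of
    labels after planting; sequences are never modified by noise.
    """

    causal_motif: str = "TATAAT"
    placement_window: int = 2
    background_gc: float = 0.5
    decoy_motifs: tuple[str, ...] = ()
    label_noise: float = 0.0

    def __post_init__(self):
        for m in (self.causal_motif, *self.decoy_motifs):
            if not m or not set(m) <= set("ACGT"):
                raise InvalidArgumentError(
                    f"motif {m!r} must be a non-empty string over ACGT"
                )
        if not 0.0 <= self.background_gc <= 1.0:
            raise InvalidArgumentError("background_gc must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise InvalidArgumentError("label_noise must lie in [0, 1]")
        if self.placement_window < 0:
            raise InvalidArgumentError("placement_window must be >= 0")

    def validate_for_length(self, L: int) -> None:
        k = len(self.causal_motif)
        if k >= L or k + 2 * self.placement_window > L:
            raise InvalidArgumentError(
                f"motif of length {k} with placement_window "
                f"{self.placement_window} does not fit in sequences of length {L}"
            )


_REJECTION_CAP = 1000


def _background(rng: np.random.Generator, n: int, L: int, gc: float) -> np.ndarray:
    """i.i.d. background as an (n, L) array of base characters."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=(n, L), p=p)
    return _BASES[idx]


def _plant(row: np.ndarray, motif: str, start: int) -> None:
    row[start : start + len(motif)] = list(motif)


def _causal_starts(L: int, motif: MotifModel) -> tuple[int, int]:
    """Inclusive start range placing the motif centre within the window."""
    centre = L // 2
    k = len(motif.causal_motif)
    lo = max(0, centre - motif.placement_window - k // 2)
    hi = min(L - k, centre + motif.placement_window - k // 2)
    if hi < lo:
        raise InvalidArgumentError("placement window admits no motif position")
    return lo, hi


def _generate_split(
    name: str, n: int, L: int, motif: MotifModel, rng: np.random.Generator
) -> DatasetSplit:
    half = n // 2
    lo, hi = _causal_starts(L, motif)
    seqs: list[str] = []
    labels: list[int] = []

    def add_decoys(row: np.ndarray) -> None:
        for d in motif.decoy_motifs:
            _plant(row, d, int(rng.integers(0, L - len(d) + 1)))

    # pathogenic: background (+decoys), causal motif planted last so the
    # signal is never destroyed by a decoy
    for _ in range(half):
        row = _background(rng, 1, L, motif.background_gc)[0]
        add_decoys(row)
        _plant(row, motif.causal_motif, int(rng.integers(lo, hi + 1)))
        seqs.append("".join(row))
        labels.append(1)
    # benign: rejection-sample until the causal motif is absent anywhere
    for _ in range(half):
        for _attempt in range(_REJECTION_CAP):
            row = _background(rng, 1, L, motif.background_gc)[0]
            add_decoys(row)
            s = "".join(row)
            if motif.causal_motif not in s:
                seqs.append(s)
                labels.append(0)
                break
        else:
            raise GenerationError(
                f"could not sample a motif-free benign background in "
                f"{_REJECTION_CAP} attempts (motif {motif.causal_motif!r}, L={L})"
            )

    order = rng.permutation(n)
    labels_arr = np.array(labels)
    if motif.label_noise > 0:
        n_flip = int(round(motif.label_noise * n))
        flip = rng.choice(n, size=n_flip, replace=False)
        labels_arr[flip] = 1 - labels_arr[flip]

    records = tuple(
        VariantRecord(
            id=f"{name}-{j:06d}",
            sequence=seqs[order[j]],
            label=int(labels_arr[order[j]]),
        )
        for j in range(n)
    )
    return DatasetSplit(name=name, records=records, L=L)


def generate_dataset(
    n_train: int,
    n_val: int,
    n_test: int,
    L: int,
    motif_model: MotifModel | None = None,
    seed: int = 0,
) -> tuple[DatasetSplit, DatasetSplit, DatasetSplit]:
    """Generate train/validation/test splits with a planted causal motif.

    Each split is exactly class-balanced before label noise, which is why
    the counts must be even. Generation is a pure function of the
    arguments and ``seed``.
    """
    motif = motif_model if motif_model is not None else MotifModel()
    for label, n in (("n_train", n_train), ("n_val", n_val), ("n_test", n_test)):
        if n < 2 or n % 2 != 0:
            raise InvalidArgumentError(f"{label}={n} must be even and >= 2")
    motif.validate_for_length(L)
    root = np.random.SeedSequence([int(seed), 0x5EB])
    streams = root.spawn(3)
    return (
        _generate_split("train", n_train, L, motif, np.random.default_rng(streams[0])),
        _generate_split("validation", n_val, L, motif, np.random.default_rng(streams[1])),
        _generate_split("test", n_test, L, motif, np.random.default_rng(streams[2])),
    )


# ---------------------------------------------------------------------------
# serialization

_HEADER = ["id", "sequence", "label"]


def write_dataset(split: DatasetSplit, path: str | Path) -> Path:
    """Write a split as CSV with the exact header ``id,sequence,label``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for rec in split.records:
            writer.writerow([rec.id, rec.sequence, rec.label])
    return path


def read_dataset(path: str | Path, name: str | None = None) -> DatasetSplit:
    """Read a CSV split; inverse of :func:`write_dataset`.

    'N' is accepted on read (real data contains ambiguous bases) even
    though the generator never emits it.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header {_HEADER}")
        if header != _HEADER:
            raise ParseError(
                f"{path}: line 1: expected header {_HEADER}, found {header}"
            )
        records: list[VariantRecord] = []
        L = None
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, found {len(row)}")
            rid, seq, label_s = row
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise ParseError(
                    f"{path}: line {lineno}: non-alphabet character(s) "
                    f"{sorted(bad)} in sequence"
                )
            if label_s not in ("0", "1"):
                raise ParseError(f"{path}: line {lineno}: label {label_s!r} is not 0/1")
            if L is None:
                L = len(seq)
            elif len(seq) != L:
                raise ParseError(
                    f"{path}: line {lineno}: sequence length {len(seq)} != {L}"
                )
            records.append(VariantRecord(rid, seq, int(label_s)))
    if not records:
        raise ParseError(f"{path}: no records after header")
    split_name = name if name is not None else path.stem
    try:
        return DatasetSplit(name=split_name, records=tuple(records), L=L)
    except InvalidArgumentError as exc:  # e.g. duplicate ids
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta(split: DatasetSplit, fasta_path: str | Path, labels_path: str | Path) -> None:
    """Export a split as FASTA plus a two-column (id, label) TSV sidecar."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    fasta_path, labels_path = Path(fasta_path), Path(labels_path)
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in split.records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    with open(labels_path, "w") as fh:
        for rec in split.records:
            fh.write(f"{rec.id}\t{rec.label}\n")


def read_fasta(
    fasta_path: str | Path, labels_path: str | Path, name: str = "fasta"
) -> DatasetSplit:
    """Read a FASTA + label-sidecar pair back into a split."""
    from Bio import SeqIO

    labels: dict[str, int] = {}
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ParseError(f"{labels_path}: line {lineno}: expected 'id<TAB>0|1'")
            labels[parts[0]] = int(parts[1])
    records = []
    for sr in SeqIO.parse(str(fasta_path), "fasta"):
        if sr.id not in labels:
            raise ParseError(f"{fasta_path}: record {sr.id!r} missing from label sidecar")
        records.append(VariantRecord(sr.id, str(sr.seq).upper(), labels[sr.id]))
    if not records:
        raise ParseError(f"{fasta_path}: no FASTA records")
    return DatasetSplit(name=name, records=tuple(records), L=len(records[0].sequence))


# ---------------------------------------------------------------------------
# real-benchmark loader (adapter contract; needs the `datasets` library)


def load_benchmark_split(
    accession: str = BENCHMARK_ACCESSION,
    split_name: str = "train",
    task: str = BENCHMARK_TASK,
    cache_dir: str | Path | None = None,
    sequence_length: int = 2048,
) -> DatasetSplit:
    """Load one split of the eQTL causal-variant benchmark.

    If ``cache_dir`` contains a previously exported ``<split_name>.csv``
    the split is read from there without any network access. Otherwise the
    Hugging Face ``datasets`` library is required and must be able to reach
    the accession; its absence or a download failure raises
    :class:`ResourceError`, while an invalid split name raises
    :class:`UnknownSplitError` before any retrieval is attempted.
    """
    if split_name not in BENCHMARK_SPLITS:
        raise UnknownSplitError(
            f"unknown split {split_name!r}; valid splits: {BENCHMARK_SPLITS}"
        )
    if cache_dir is not None:
        cached = Path(cache_dir) / f"{split_name}.csv"
        if cached.exists():
            split = read_dataset(cached, name=split_name)
            _log_counts(split)
            return split
    try:
        import datasets as hf_datasets  # type: ignore
    except ImportError as exc:
        raise ResourceError(
            f"loading {accession!r} requires the 'datasets' library, which is "
            "not installed; pass cache_dir pointing at an exported CSV instead"
        ) from exc
    try:
        ds = hf_datasets.load_dataset(
            accession,
            task_name=task,
            split=split_name,
            sequence_length=sequence_length,
            cache_dir=str(cache_dir) if cache_dir else None,
        )
    except Exception as exc:  # network / accession failures
        raise ResourceError(f"could not retrieve {accession!r}: {exc}") from exc
    records = tuple(
        VariantRecord(
            id=f"{split_name}-{i:06d}",
            sequence=str(row["sequence"]).upper(),
            label=int(row["label"]),
        )
        for i, row in enumerate(ds)
    )
    split = DatasetSplit(
        name=split_name, records=records, L=len(records[0].sequence)
    )
    _log_counts(split)
    return split


def _log_counts(split: DatasetSplit) -> None:
    neg, pos = split.class_counts()
    logger.info(
        "split %s: %d records (%d benign, %d pathogenic)",
        split.name, len(split), neg, pos,
    )


def subsample_split(split: DatasetSplit, n: int, seed: int = 0) -> DatasetSplit:
    """Seeded class-stratified subsample, for desk-scale work on real data."""
    if n < 2 or n > len(split):
        raise InvalidArgumentError(f"n={n} out of range for split of {len(split)}")
    rng = np.random.default_rng(seed)
    labels = split.labels
    keep: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        k = min(len(idx), n // 2)
        keep.extend(rng.choice(idx, size=k, replace=False).tolist())
    keep.sort()
    return DatasetSplit(
        name=split.name,
        records=tuple(split.records[i] for i in keep),
        L=split.L,
    )
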