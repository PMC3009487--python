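"""Readers and writers: FASTA, score-matrix TSV, experiment splits,
trained-model JSON, and the run configuration.

All text outputs can carry a provenance header (tool version, seed,
config hash) as ``#`` comment lines, and every reader skips such lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .classify import ExperimentSplit, TrainedModel
from .pattern import PROTEIN_ALPHABET, Sequence, validate_sequence
from .scoring import ScoreMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_score_matrix",
    "read_score_matrix",
    "load_split",
    "save_model",
    "load_model",
    "RunConfig",
    "provenance_lines",
]

logger = logging.getLogger(__name__)


def _alphabet_options(mode: str) -> dict:
    """Map an alphabet-mode name to validate_sequence options."""
    if mode == "protein":
        return dict(alphabet=PROTEIN_ALPHABET, case_fold=True, strict=True)
    if mode == "protein-permissive":
        return dict(alphabet=PROTEIN_ALPHABET, case_fold=True, strict=False)
    if mode == "generic":
        return dict(alphabet=None, case_fold=False, strict=True)
    raise ValueError(f"unknown alphabet mode {mode!r}")


def read_fasta(
    path,
    *,
    alphabet_mode: str = "protein",
    on_duplicate: str = "error",
) -> list[Sequence]:
    """Read a multi-record FASTA file into validated sequences.

    The record id is the description line up to the first whitespace.
    Duplicate ids either raise (``error``) or keep the first record with a
    warning (``warn``).
    """
    options = _alphabet_options(alphabet_mode)
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with a blank description line")
        if rec.id in seen:
            if on_duplicate == "error":
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            logger.warning("%s: duplicate id %r skipped", path, rec.id)
            continue
        seen.add(rec.id)
        seqs.append(validate_sequence(str(rec.seq), id=rec.id, **options))
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: list[Sequence], path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def provenance_lines(*, seed: int | None = None, config_hash: str | None = None) -> tuple[str, ...]:
    """Comment lines recording tool version and run provenance."""
    parts = [f"irredclass {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return (" ".join(parts),)


def write_score_matrix(
    M: ScoreMatrix, path, *, comments: tuple[str, ...] = ()
) -> None:
    """Write a score matrix as TSV with an id header row and column.

    Values are written with ``repr`` so the round-trip is bit-exact.
    """
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("id\t" + "\t".join(M.ids) + "\n")
        for i, row_id in enumerate(M.ids):
            fh.write(
                row_id + "\t" + "\t".join(repr(float(v)) for v in M.values[i]) + "\n"
            )


def read_score_matrix(path) -> ScoreMatrix:
    ids: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    row_ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if ids is None:
                ids = tuple(parts[1:])
                continue
            row_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if ids is None or tuple(row_ids) != ids:
        raise ValueError(f"{path}: malformed score matrix")
    return ScoreMatrix(ids=ids, values=np.array(rows))


_SPLIT_FILES = {
    "pos_train": "pos_train",
    "neg_train": "neg_train",
    "pos_test": "pos_test",
    "neg_test": "neg_test",
}


def load_split(path, *, family: str | None = None) -> ExperimentSplit:
    """Load an experiment split.

    Two dialects are accepted: a directory with four id-list files
    (``pos_train``, ``neg_train``, ``pos_test``, ``neg_test``, optionally
    with a ``.txt`` suffix), or a single TSV with columns
    ``id``, ``split`` (train/test), ``label`` (pos/neg or +-1).
    """
    p = Path(path)
    if p.is_dir():
        lists: dict[str, tuple[str, ...]] = {}
        for key, stem in _SPLIT_FILES.items():
            candidates = [p / stem, p / f"{stem}.txt"]
            f = next((c for c in candidates if c.exists()), None)
            if f is None:
                raise FileNotFoundError(f"{p}: missing split file {stem}[.txt]")
            lists[key] = tuple(
                line.strip() for line in f.read_text().splitlines() if line.strip()
            )
        return ExperimentSplit(family=family or p.name, **lists)
    lists2: dict[str, list[str]] = {k: [] for k in _SPLIT_FILES}
    with open(p) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seq_id, split, label = line.rstrip("\n").split("\t")[:3]
            if seq_id == "id":
                continue
            pos = label in ("pos", "1", "+1")
            key = ("pos_" if pos else "neg_") + split
            if key not in lists2:
                raise ValueError(f"{p}: bad split/label pair {split!r}/{label!r}")
            lists2[key].append(seq_id)
    return ExperimentSplit(
        family=family or p.stem,
        **{k: tuple(v) for k, v in lists2.items()},
    )


def save_model(model: TrainedModel, path) -> None:
    payload = {
        "train_ids": list(model.train_ids),
        "alpha": model.alpha.tolist(),
        "labels": model.labels.tolist(),
        "bias": model.bias,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    return TrainedModel(
        train_ids=tuple(payload["train_ids"]),
        alpha=np.array(payload["alpha"], dtype=float),
        labels=np.array(payload["labels"], dtype=int),
        bias=float(payload["bias"]),
    )


@dataclass
class RunConfig:
    """Run-level configuration, round-trippable through a key=value file."""

    alphabet_mode: str = "protein"
    background: str = "blosum62"
    kernel_mode: str = "raw"
    max_iter: int = 1_000_000
    svm_c: float = 1.0
    log_level: str = "INFO"
    log_every: int = 100

    def to_file(self, path) -> None:
        lines = [
            f"{f.name}={getattr(self, f.name)}" for f in fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            kwargs[key] = type(current)(value.strip())
        return cls(**kwargs)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
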