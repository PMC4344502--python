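"""Hairpin reference: precursor sequences plus located mature arms.

Coordinates are 0-based half-open on the precursor. Sequences are
canonicalized to the DNA alphabet (U -> T) at load time; the original
alphabet (RNA vs DNA) is remembered per record so writers can round-trip.
The loop interval is derived as the gap between the 5p arm end and the
3p arm start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGT")
ARMS = ("5p", "3p")


class ReferenceError(ValueError):
    """Invalid reference input (bad interval, unknown hairpin, bad alphabet)."""


def canonicalize(seq: str) -> str:
    """Uppercase and map U -> T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MatureAnnotation:
    mature_id: str
    arm: str          # "5p" or "3p"
    start: int        # 0-based inclusive
    end: int          # 0-based exclusive


@dataclass
class HairpinRecord:
    """A precursor with its annotated mature arm(s)."""

    hairpin_id: str
    sequence: str                                  # canonical DNA, uppercase
    mature: dict = field(default_factory=dict)     # arm -> MatureAnnotation
    rna_input: bool = False                        # original FASTA used U

    @property
    def loop(self):
        """(start, end) between the arms, or None for single-arm hairpins."""
        if "5p" in self.mature and "3p" in self.mature:
            return (self.mature["5p"].end, self.mature["3p"].start)
        return None

    def mature_seq(self, arm: str) -> str:
        ann = self.mature[arm]
        return self.sequence[ann.start:ann.end]

    def validate(self) -> None:
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise ReferenceError(
                f"hairpin {self.hairpin_id!r}: non-ACGTU characters {sorted(bad)}")
        for arm, ann in self.mature.items():
            if arm not in ARMS:
                raise ReferenceError(f"hairpin {self.hairpin_id!r}: bad arm {arm!r}")
            if not (0 <= ann.start < ann.end <= len(self.sequence)):
                raise ReferenceError(
                    f"mature {ann.mature_id!r}: interval [{ann.start},{ann.end}) "
                    f"outside hairpin {self.hairpin_id!r} of length {len(self.sequence)}")
        if "5p" in self.mature and "3p" in self.mature:
            if self.mature["5p"].end > self.mature["3p"].start:
                raise ReferenceError(
                    f"hairpin {self.hairpin_id!r}: 5p arm must precede 3p arm")


class Reference:
    """Collection of hairpin records with cross-reference groups.

    Mature arms sharing an identical sequence (e.g. paralogous
    precursors) are collapsed into one cross-reference group; quantified
    reads are attributed once per group, keyed by the group's canonical
    (lexicographically first) mature id.
    """

    def __init__(self, hairpins):
        self.hairpins = list(hairpins)
        self.by_id = {}
        for hp in self.hairpins:
            if hp.hairpin_id in self.by_id:
                raise ReferenceError(f"duplicate hairpin id {hp.hairpin_id!r}")
            hp.validate()
            self.by_id[hp.hairpin_id] = hp
        # sequence -> sorted list of mature ids sharing it
        groups: dict = {}
        for hp in self.hairpins:
            for arm, ann in hp.mature.items():
                groups.setdefault(hp.mature_seq(arm), []).append(ann.mature_id)
        self.xref_groups = {seq: sorted(ids) for seq, ids in groups.items()}
        self.group_of = {mid: ids[0] for ids in self.xref_groups.values() for mid in ids}

    def __len__(self):
        return len(self.hairpins)

    def __iter__(self):
        return iter(self.hairpins)

    def mature_table(self) -> pd.DataFrame:
        rows = []
        for hp in self.hairpins:
            for arm in ARMS:
                if arm in hp.mature:
                    ann = hp.mature[arm]
                    rows.append({
                        "hairpin_id": hp.hairpin_id, "mature_id": ann.mature_id,
                        "arm": arm, "start": ann.start, "end": ann.end,
                        "sequence": hp.mature_seq(arm),
                        "group_id": self.group_of[ann.mature_id],
                    })
        return pd.DataFrame(
            rows, columns=["hairpin_id", "mature_id", "arm", "start", "end",
                           "sequence", "group_id"])


def load_reference(hairpin_fasta, annotation_tsv) -> Reference:
    """Read a hairpin FASTA and a mature-arm annotation table.

    The annotation TSV has columns ``hairpin_id, mature_id, arm, start,
    end`` with 0-based half-open coordinates on the hairpin. Every row
    must name a hairpin present in the FASTA.
    """
    records = {}
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        raw = str(rec.seq)
        records[rec.id] = HairpinRecord(
            hairpin_id=rec.id, sequence=canonicalize(raw),
            rna_input="U" in raw.upper())
    annot = pd.read_csv(annotation_tsv, sep="\t", dtype={"arm": str})
    required = {"hairpin_id", "mature_id", "arm", "start", "end"}
    missing = required - set(annot.columns)
    if missing:
        raise ReferenceError(f"annotation table missing columns: {sorted(missing)}")
    for row in annot.itertuples(index=False):
        if row.hairpin_id not in records:
            raise ReferenceError(
                f"annotation row for mature {row.mature_id!r} references "
                f"unknown hairpin {row.hairpin_id!r}")
        hp = records[row.hairpin_id]
        if row.arm in hp.mature:
            raise ReferenceError(
                f"hairpin {row.hairpin_id!r}: duplicate annotation for arm {row.arm!r}")
        hp.mature[row.arm] = MatureAnnotation(
            mature_id=str(row.mature_id), arm=str(row.arm),
            start=int(row.start), end=int(row.end))
    return Reference(records.values())


def write_reference(reference: Reference, fasta_path, annotation_path) -> None:
    """Write the hairpin FASTA and the mature annotation TSV."""
    recs = []
    for hp in reference:
        seq = hp.sequence.replace("T", "U") if hp.rna_input else hp.sequence
        recs.append(SeqRecord(Seq(seq), id=hp.hairpin_id, description=""))
    SeqIO.write(recs, str(fasta_path), "fasta")
    cols = ["hairpin_id", "mature_id", "arm", "start", "end"]
    reference.mature_table()[cols].to_csv(annotation_path, sep="\t", index=False)


def write_fasta(seqs: dict, path) -> None:
    """Write a plain {id: sequence} mapping as FASTA."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_sequences(path) -> list:
    """Read FASTA or FASTQ read sequences (qualities ignored), canonicalized."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    return [canonicalize(str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
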