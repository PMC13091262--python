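"""Reading and writing the benchmark's on-disk formats.

Alignments go out as aligned FASTA (gap ``-``) and Stockholm via
Biopython; ground truth travels in a TSV sidecar with header
``sbre<TAB>start<TAB>end`` using 1-based inclusive alignment columns.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence, Union

from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import AlignIO

from .synthetic import Dataset, RegionAnnotation, SyntheticMSA

PathLike = Union[str, Path]

GROUND_TRUTH_COLUMNS = ("sbre", "start", "end")


def _to_biopython(msa: SyntheticMSA) -> MultipleSeqAlignment:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in zip(msa.ids, msa.sequences)
    ]
    return MultipleSeqAlignment(records)


def write_alignment_fasta(msa: SyntheticMSA, path: PathLike) -> None:
    AlignIO.write(_to_biopython(msa), str(path), "fasta")


def write_alignment_stockholm(msa: SyntheticMSA, path: PathLike) -> None:
    AlignIO.write(_to_biopython(msa), str(path), "stockholm")


def read_alignment_fasta(path: PathLike) -> SyntheticMSA:
    alignment = AlignIO.read(str(path), "fasta")
    return SyntheticMSA(sequences=tuple(str(rec.seq) for rec in alignment))


def write_ground_truth(dataset_or_regions, path: PathLike) -> None:
    """Write the ground-truth TSV sidecar, rows sorted by start."""
    if isinstance(dataset_or_regions, Dataset):
        regions: Sequence[RegionAnnotation] = dataset_or_regions.regions
    else:
        regions = dataset_or_regions
    regions = sorted(regions, key=lambda r: r.start)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GROUND_TRUTH_COLUMNS)
        for region in regions:
            writer.writerow([region.sbre, region.start, region.end])


def read_ground_truth(path: PathLike) -> list[RegionAnnotation]:
    """Read a ground-truth sidecar back into region annotations."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != GROUND_TRUTH_COLUMNS:
            raise ValueError(
                f"{path}: expected header {list(GROUND_TRUTH_COLUMNS)}, got {header}"
            )
        regions = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            sbre, start, end = row
            try:
                regions.append(
                    RegionAnnotation(sbre=sbre, start=int(start), end=int(end))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer boundary") from exc
    return regions
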