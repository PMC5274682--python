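"""Readers and writers: FASTA, BED6, GFF3, bedGraph, TSV, matrix files.

Coordinates are 1-based inclusive inside the library and converted to
0-based half-open at the BED/bedGraph boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import PeriodicAlignment
from .density import DensityProfile
from .matrices import BASES, FrequencyMatrix, WeightMatrix
from .scan import PeriodicRegion
from .sequence import ALPHABET, NucleotideSequence

logger = logging.getLogger(__name__)

_VALID = set(ALPHABET)


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file; non-ACGTN symbols are mapped to N."""
    out: list[NucleotideSequence] = []
    replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        cleaned = "".join(c if c in _VALID else "N" for c in raw)
        replaced += sum(1 for a, b in zip(raw, cleaned) if a != b)
        out.append(NucleotideSequence(rec.id, cleaned))
    if replaced:
        logger.info("mapped %d non-ACGTN symbols to N", replaced)
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(sequences: list[NucleotideSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- matrices

def write_weight_matrix(M: WeightMatrix, path: str | Path) -> None:
    """TSV with 4 base-labeled rows x n columns."""
    pd.DataFrame(M.weights, index=list(BASES)).to_csv(path, sep="\t", header=True)


def read_weight_matrix(path: str | Path) -> WeightMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return WeightMatrix(df.loc[list(BASES)].to_numpy(dtype=float))


def write_frequency_matrix(F: FrequencyMatrix, path: str | Path) -> None:
    pd.DataFrame(F.counts, index=list(BASES)).to_csv(path, sep="\t", header=True)


def read_frequency_matrix(path: str | Path) -> FrequencyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FrequencyMatrix(df.loc[list(BASES)].to_numpy(dtype=float))


def read_frequency_matrix_dir(path: str | Path) -> list[FrequencyMatrix]:
    files = sorted(Path(path).glob("*.tsv"))
    if not files:
        raise ValueError(f"no matrix TSV files in {path}")
    return [read_frequency_matrix(f) for f in files]


# ---------------------------------------------------------------- alignments

def format_alignment(
    alignment: PeriodicAlignment, S: NucleotideSequence, width: int = 60
) -> str:
    """Three-line blocks: sequence / match bars / period column indices."""
    seq_line = []
    bar_line = []
    col_line = []
    for step in alignment.path:
        if step[0] == "M":
            _, pos, col, _ = step
            seq_line.append(S.residues[pos - 1])
            bar_line.append("|")
            col_line.append(str((col - 1) % 10))
        elif step[0] == "I":
            seq_line.append(S.residues[step[1] - 1])
            bar_line.append(" ")
            col_line.append("-")
        else:
            seq_line.append("-")
            bar_line.append(" ")
            col_line.append(str((step[1] - 1) % 10))
    blocks = []
    for i in range(0, len(seq_line), width):
        blocks.append(
            "".join(seq_line[i : i + width])
            + "\n"
            + "".join(bar_line[i : i + width])
            + "\n"
            + "".join(col_line[i : i + width])
        )
    head = (
        f"# score={alignment.score:.2f} seq={alignment.seq_start}-"
        f"{alignment.seq_end} phase={alignment.phase}\n"
    )
    return head + "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------- regions

_TSV_COLUMNS = [
    "seq_id", "start", "end", "period", "mF_max", "z", "triplet_Z", "consensus",
]


def regions_to_frame(regions: list[PeriodicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": r.seq_id,
                "start": r.start,
                "end": r.end,
                "period": r.n,
                "mF_max": r.mF_max,
                "z": np.nan if r.z is None else r.z,
                "triplet_Z": r.triplet_Z,
                "consensus": r.consensus,
            }
            for r in regions
        ],
        columns=_TSV_COLUMNS,
    )


def write_regions(
    regions: list[PeriodicRegion],
    prefix: str | Path,
    formats: tuple[str, ...] = ("tsv", "bed", "gff3"),
    matrices: bool = False,
) -> dict[str, Path]:
    """Write a region set under ``prefix`` in the requested formats.

    BED6: 0-based half-open, name "period=n", score round(mF_max) capped at
    1000.  GFF3: 1-based inclusive with period/mFmax/Z/consensus attributes.
    With ``matrices=True`` sidecar weight/frequency matrix TSVs and
    alignment dumps are written per region.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if "tsv" in formats:
        p = prefix.with_suffix(".tsv")
        regions_to_frame(regions).to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["tsv"] = p
    if "bed" in formats:
        p = prefix.with_suffix(".bed")
        with open(p, "w") as fh:
            for r in regions:
                score = min(1000, int(round(r.mF_max)))
                fh.write(
                    f"{r.seq_id}\t{r.start - 1}\t{r.end}\tperiod={r.n}\t{score}\t+\n"
                )
        written["bed"] = p
    if "gff3" in formats:
        p = prefix.with_suffix(".gff3")
        with open(p, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, r in enumerate(regions, 1):
                attrs = (
                    f"ID=region{i};period={r.n};mFmax={r.mF_max:.2f};"
                    f"Z={r.triplet_Z:.2f};consensus={r.consensus}"
                )
                fh.write(
                    f"{r.seq_id}\tlatentscan\ttandem_repeat\t{r.start}\t{r.end}\t"
                    f"{r.mF_max:.2f}\t+\t.\t{attrs}\n"
                )
        written["gff3"] = p
    if matrices:
        mdir = prefix.parent / (prefix.name + "_matrices")
        mdir.mkdir(exist_ok=True)
        for i, r in enumerate(regions, 1):
            write_weight_matrix(r.matrix, mdir / f"region{i}_weights.tsv")
            write_frequency_matrix(r.freq, mdir / f"region{i}_freq.tsv")
            if r.alignment.path:
                (mdir / f"region{i}_alignment.txt").write_text(
                    _alignment_block(r.alignment)
                )
        written["matrices"] = mdir
    return written


def _alignment_block(alignment: PeriodicAlignment, width: int = 60) -> str:
    """Alignment dump when only the path (with base codes) is at hand."""
    seq_line, bar_line, col_line = [], [], []
    for step in alignment.path:
        if step[0] == "M":
            seq_line.append(ALPHABET[step[3]])
            bar_line.append("|")
            col_line.append(str((step[2] - 1) % 10))
        elif step[0] == "I":
            seq_line.append("*")
            bar_line.append(" ")
            col_line.append("-")
        else:
            seq_line.append("-")
            bar_line.append(" ")
            col_line.append(str((step[1] - 1) % 10))
    head = (
        f"# score={alignment.score:.2f} seq={alignment.seq_start}-"
        f"{alignment.seq_end} phase={alignment.phase}\n"
    )
    blocks = [
        "".join(seq_line[i : i + width]) + "\n"
        + "".join(bar_line[i : i + width]) + "\n"
        + "".join(col_line[i : i + width])
        for i in range(0, len(seq_line), width)
    ]
    return head + "\n\n".join(blocks) + "\n"


def read_regions_tsv(path: str | Path) -> list[PeriodicRegion]:
    """Read back a region TSV (matrices/alignments are not round-tripped)."""
    from .align import EMPTY_ALIGNMENT

    df = pd.read_csv(path, sep="\t")
    regions = []
    for row in df.itertuples():
        n = int(row.period)
        regions.append(
            PeriodicRegion(
                seq_id=str(row.seq_id),
                start=int(row.start),
                end=int(row.end),
                n=n,
                mF_max=float(row.mF_max),
                triplet_Z=float(row.triplet_Z),
                matrix=WeightMatrix(np.zeros((4, n))),
                freq=FrequencyMatrix(np.zeros((4, n))),
                consensus=str(row.consensus),
                alignment=EMPTY_ALIGNMENT,
                z=None if pd.isna(row.z) else float(row.z),
            )
        )
    return regions


def read_regions_bed(path: str | Path) -> list[PeriodicRegion]:
    """Read a BED interval file as bare regions (period parsed from name)."""
    from .align import EMPTY_ALIGNMENT

    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            n = 2
            if name.startswith("period="):
                n = max(2, int(name.split("=", 1)[1]))
            regions.append(
                PeriodicRegion(
                    seq_id=chrom,
                    start=start0 + 1,
                    end=end,
                    n=n,
                    mF_max=score,
                    triplet_Z=0.0,
                    matrix=WeightMatrix(np.zeros((4, n))),
                    freq=FrequencyMatrix(np.zeros((4, n))),
                    consensus="",
                    alignment=EMPTY_ALIGNMENT,
                )
            )
    return regions


# ---------------------------------------------------------------- profiles

def write_profile(profile: DensityProfile, prefix: str | Path) -> dict[str, Path]:
    """bedGraph (0-based half-open) and TSV (bin index, start, end, sum)."""
    prefix = Path(prefix)
    paths = {}
    bg = prefix.with_suffix(".bedgraph")
    tsv = prefix.with_suffix(".tsv")
    with open(bg, "w") as fh:
        for i, v in enumerate(profile.bins):
            s, e = profile.bin_interval(i)
            fh.write(f"{profile.seq_id}\t{s - 1}\t{e}\t{v:.2f}\n")
    with open(tsv, "w") as fh:
        fh.write("bin\tstart\tend\tsum_fmax\n")
        for i, v in enumerate(profile.bins):
            s, e = profile.bin_interval(i)
            fh.write(f"{i}\t{s}\t{e}\t{v:.2f}\n")
    paths["bedgraph"] = bg
    paths["tsv"] = tsv
    return paths
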