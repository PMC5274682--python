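"""Synthetic latent-periodicity data with known truth.

The generator emulates the regime that defines latent periodicity: a
tandem array of a consensus unit degraded by, on average, one or more
substitutions per nucleotide plus insertions and deletions, embedded in
random background.  Substitutions are applied as repeated mutation rounds
(Poisson number of events per base, each to a uniformly chosen different
base), so a base can mutate more than once and identity to the consensus
saturates near 25% — the regime where no pair of periods shows significant
similarity and only profile methods can recover the period.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence import ALPHABET, NucleotideSequence, from_codes

_BASE_CODE = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class ImplantSpec:
    consensus: str  # the repeat unit; its length is the true period
    copies: int
    substitution_rate: float = 1.0  # expected substitution events per nucleotide
    indel_rate: float = 0.05  # expected indel events per nucleotide
    indel_max_len: int = 3
    background_length: int = 3000  # total emitted sequence length
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.consensus or set(self.consensus.upper()) - set("ACGT"):
            raise ValueError("consensus must be a non-empty string over ACGT")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ValueError("mutation rates must be non-negative")
        object.__setattr__(self, "consensus", self.consensus.upper())

    @property
    def period(self) -> int:
        return len(self.consensus)

    def effective_substitution_probability(self) -> float:
        """P(base differs from consensus) after Poisson mutation rounds.

        Repeated uniform mutation is the Jukes-Cantor chain:
        p = 3/4 (1 - exp(-4 r / 3)).
        """
        return 0.75 * (1.0 - np.exp(-4.0 * self.substitution_rate / 3.0))


@dataclass(frozen=True)
class SyntheticTruth:
    implant_start: int  # 1-based inclusive
    implant_end: int
    true_period: int
    substitutions: int  # bases differing from the consensus tiling
    insertions: int  # inserted bases
    deletions: int  # deleted bases


def _mutate_array(
    spec: ImplantSpec, rng: np.random.Generator
) -> tuple[np.ndarray, int, int, int]:
    unit = np.array([_BASE_CODE[b] for b in spec.consensus], dtype=np.int64)
    arr = np.tile(unit, spec.copies)
    events = rng.poisson(spec.substitution_rate, size=arr.size)
    for i in np.nonzero(events)[0]:
        for _ in range(events[i]):
            arr[i] = (arr[i] + rng.integers(1, 4)) % 4
    n_sub = int(np.sum(arr != np.tile(unit, spec.copies)))
    # indel events per base position; insert after or delete starting at it
    out: list[int] = []
    n_ins = n_del = 0
    skip = 0
    for i, b in enumerate(arr):
        if skip > 0:
            skip -= 1
            continue
        if rng.random() < spec.indel_rate:
            length = int(rng.integers(1, spec.indel_max_len + 1))
            if rng.random() < 0.5:
                out.append(int(b))
                out.extend(int(x) for x in rng.integers(0, 4, size=length))
                n_ins += length
            else:
                skip = length - 1
                n_del += min(length, arr.size - i)
                continue
        else:
            out.append(int(b))
    return np.array(out, dtype=np.int8), n_sub, n_ins, n_del


def tandem_array(spec: ImplantSpec) -> NucleotideSequence:
    """The mutated tandem array alone, without background embedding."""
    rng = np.random.default_rng(spec.seed)
    implant, *_ = _mutate_array(spec, rng)
    return from_codes(implant, id=f"array_p{spec.period}_s{spec.seed}")


def simulate_latent_periodic(spec: ImplantSpec) -> tuple[NucleotideSequence, SyntheticTruth]:
    """Emit a background sequence with a mutated tandem array implanted.

    The emitted sequence has length ``background_length``; a seeded random
    stretch of it is replaced by the mutated array.
    """
    rng = np.random.default_rng(spec.seed)
    implant, n_sub, n_ins, n_del = _mutate_array(spec, rng)
    L = spec.background_length
    if L < implant.size:
        raise ValueError(
            f"background_length {L} shorter than mutated implant ({implant.size} nt)"
        )
    p = np.asarray(spec.background_composition, dtype=float)
    p = p / p.sum()
    background = rng.choice(4, size=L, p=p).astype(np.int8)
    offset = int(rng.integers(0, L - implant.size + 1))
    background[offset : offset + implant.size] = implant
    seq = from_codes(background, id=f"synthetic_p{spec.period}_s{spec.seed}")
    truth = SyntheticTruth(
        implant_start=offset + 1,
        implant_end=offset + implant.size,
        true_period=spec.period,
        substitutions=n_sub,
        insertions=n_ins,
        deletions=n_del,
    )
    return seq, truth


def make_benchmark(
    specs: list[ImplantSpec],
    out_dir: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write a FASTA + truth BED + manifest TSV benchmark fixture set.

    One FASTA record per spec; the BED (0-based half-open) holds the true
    implant intervals; the manifest allows the grid to be reconstructed.
    """
    out = Path(out_dir)
    manifest = out / "manifest.tsv"
    if manifest.exists() and not overwrite:
        raise FileExistsError(f"{manifest} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    fasta_lines: list[str] = []
    bed_lines: list[str] = []
    rows: list[str] = []
    header = (
        "record\tconsensus\tcopies\tsubstitution_rate\tindel_rate\t"
        "indel_max_len\tbackground_length\tseed\timplant_start\timplant_end\ttrue_period"
    )
    for spec in specs:
        seq, truth = simulate_latent_periodic(spec)
        fasta_lines.append(f">{seq.id}")
        fasta_lines.extend(
            seq.residues[i : i + 70] for i in range(0, len(seq), 70)
        )
        bed_lines.append(
            f"{seq.id}\t{truth.implant_start - 1}\t{truth.implant_end}\t"
            f"period={truth.true_period}\t0\t+"
        )
        rows.append(
            f"{seq.id}\t{spec.consensus}\t{spec.copies}\t{spec.substitution_rate}\t"
            f"{spec.indel_rate}\t{spec.indel_max_len}\t{spec.background_length}\t"
            f"{spec.seed}\t{truth.implant_start}\t{truth.implant_end}\t{truth.true_period}"
        )
    (out / "sequences.fasta").write_text("\n".join(fasta_lines) + "\n")
    (out / "truth.bed").write_text("\n".join(bed_lines) + "\n")
    manifest.write_text(header + "\n" + "\n".join(rows) + "\n")
    return out


def read_manifest(out_dir: str | Path) -> list[ImplantSpec]:
    """Reconstruct the spec grid from a benchmark manifest."""
    lines = (Path(out_dir) / "manifest.tsv").read_text().strip().split("\n")
    head = lines[0].split("\t")
    specs = []
    for line in lines[1:]:
        row = dict(zip(head, line.split("\t")))
        specs.append(
            ImplantSpec(
                consensus=row["consensus"],
                copies=int(row["copies"]),
                substitution_rate=float(row["substitution_rate"]),
                indel_rate=float(row["indel_rate"]),
                indel_max_len=int(row["indel_max_len"]),
                background_length=int(row["background_length"]),
                seed=int(row["seed"]),
            )
        )
    return specs


def random_consensus(period: int, rng: np.random.Generator) -> str:
    """A uniform-random repeat unit of the given period length."""
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=period))
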