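"""Deterministic synthetic long-read data generators.

Every generator is a pure function of its parameters and seed: a rerun
with the same arguments produces byte-identical files. Each writes a
truth table alongside its output (``<file>.truth.tsv``) recording the
exact per-read quantities it generated, so downstream statistics can be
checked against bookkeeping instead of being re-derived.

The default length model is lognormal (mu=8.5, sigma=1.0 in log-bases,
median ~4.9 kb with a long tail) emulating typical nanopore length
profiles; these generators make no attempt at realistic nanopore error
structure (no homopolymer bias, no signal-level effects).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics

BASES = np.array(list("ACGT"))

DEFAULT_LENGTH_DIST = ("lognormal", 8.5, 1.0)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(rng.choice(BASES, size=length, p=p))


def _draw_lengths(rng: np.random.Generator, n: int, length_dist) -> np.ndarray:
    kind = length_dist[0]
    if kind == "fixed":
        return np.full(n, int(length_dist[1]), dtype=np.int64)
    if kind == "lognormal":
        mu, sigma = length_dist[1], length_dist[2]
        return np.maximum(1, rng.lognormal(mu, sigma, size=n).astype(np.int64))
    raise ValueError(f"unknown length distribution {kind!r}")


def _draw_qualities(rng: np.random.Generator, length: int, quality_dist) -> np.ndarray:
    kind = quality_dist[0]
    if kind == "fixed":
        return np.full(length, int(quality_dist[1]), dtype=np.int64)
    if kind == "normal":
        mean, sd = quality_dist[1], quality_dist[2]
        q = np.rint(rng.normal(mean, sd, size=length)).astype(np.int64)
        return np.clip(q, 1, 60)
    raise ValueError(f"unknown quality distribution {kind!r}")


def _phred_string(q: np.ndarray) -> str:
    return (q + metrics.PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")


def make_fastq(path, n: int, length_dist=DEFAULT_LENGTH_DIST, quality_dist=("normal", 12, 3), gc: float = 0.5, seed: int = 1) -> tuple[Path, pd.DataFrame]:
    """Write a FASTQ of n synthetic reads plus its truth table.

    Truth columns: read_id, length, mean_quality (probability-space mean
    of the generated per-base scores), gc_fraction (over the generated
    bases, all unambiguous).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    path = Path(path)
    rng = _rng(seed)
    lengths = _draw_lengths(rng, n, length_dist)
    rows = []
    with open(path, "w") as fh:
        for i, length in enumerate(lengths):
            read_id = f"read_{i:06d}"
            seq = random_sequence(rng, int(length), gc)
            q = _draw_qualities(rng, int(length), quality_dist)
            fh.write(f"@{read_id}\n{seq}\n+\n{_phred_string(q)}\n")
            rows.append(
                {
                    "read_id": read_id,
                    "length": int(length),
                    "mean_quality": metrics.mean_read_quality(q),
                    "gc_fraction": (seq.count("G") + seq.count("C")) / len(seq),
                }
            )
    truth = pd.DataFrame(
        rows, columns=["read_id", "length", "mean_quality", "gc_fraction"]
    )
    truth.to_csv(f"{path}.truth.tsv", sep="\t", index=False)
    return path, truth


def make_summary(path, n: int, channels: int = 512, run_hours: float = 48.0, quality_drift: float = 0.0, base_quality: float = 12.0, noise_sd: float = 1.0, length_dist=DEFAULT_LENGTH_DIST, barcodes=None, seed: int = 1) -> tuple[Path, pd.DataFrame]:
    """Write a basecaller sequencing-summary TSV plus its truth table.

    Start times are uniform on [0, run_hours]; mean qscore is
    base_quality - quality_drift * hours + Gaussian noise (clipped >= 1),
    emulating the quality decline seen late in a run when drift > 0.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    path = Path(path)
    rng = _rng(seed)
    hours = rng.uniform(0.0, run_hours, size=n)
    quality = np.clip(
        base_quality - quality_drift * hours + rng.normal(0.0, noise_sd, size=n), 1.0, None
    )
    df = pd.DataFrame(
        {
            "read_id": [f"read_{i:06d}" for i in range(n)],
            "channel": rng.integers(1, channels + 1, size=n),
            "start_time": np.round(hours * 3600.0, 3),
            "sequence_length_template": _draw_lengths(rng, n, length_dist),
            "mean_qscore_template": np.round(quality, 4),
        }
    )
    if barcodes is not None:
        df["barcode_arrangement"] = rng.choice(np.asarray(barcodes), size=n)
    df.to_csv(path, sep="\t", index=False)
    truth = df.copy()
    truth["hours"] = hours
    truth.to_csv(f"{path}.truth.tsv", sep="\t", index=False)
    return path, truth


def make_alignments(path, reference_length: int = 50_000, n: int = 1000, identity: float = 0.9, partial_fraction: float = 0.0, read_length_range: tuple[int, int] = (300, 2000), seed: int = 1) -> tuple[Path, pd.DataFrame]:
    """Write a SAM of reads sampled from a generated reference, plus truth.

    Point substitutions are introduced at rate (1 - identity); NM and the
    CIGAR are consistent with the introduced edits by construction. A
    ``partial_fraction`` of reads receives soft-clipped ends (random bases
    appended outside the aligned block), so aligned_length < length for
    exactly those reads.
    """
    if not (0.0 <= identity <= 1.0):
        raise ValueError("identity must be in [0, 1]")
    if not (0.0 <= partial_fraction <= 1.0):
        raise ValueError("partial_fraction must be in [0, 1]")
    path = Path(path)
    rng = _rng(seed)
    reference = random_sequence(rng, reference_length)
    lo, hi = read_length_range
    rows = []
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:ref\tLN:{reference_length}\n")
        for i in range(n):
            read_id = f"aln_{i:06d}"
            core_len = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, reference_length - core_len))
            core = np.array(list(reference[start : start + core_len]))
            err_mask = rng.random(core_len) < (1.0 - identity)
            n_edits = int(err_mask.sum())
            if n_edits:
                # substitute with a guaranteed-different base (cyclic shift)
                idx = np.searchsorted(BASES, core[err_mask])
                core[err_mask] = BASES[(idx + rng.integers(1, 4, size=n_edits)) % 4]
            seq = "".join(core)
            clip5 = clip3 = 0
            if rng.random() < partial_fraction:
                clip5 = int(rng.integers(20, 200))
                clip3 = int(rng.integers(20, 200))
                seq = (
                    random_sequence(rng, clip5) + seq + random_sequence(rng, clip3)
                )
            cigar = (
                (f"{clip5}S" if clip5 else "")
                + f"{core_len}M"
                + (f"{clip3}S" if clip3 else "")
            )
            qual = "I" * len(seq)
            fh.write(
                f"{read_id}\t0\tref\t{start + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{seq}\t{qual}\tNM:i:{n_edits}\n"
            )
            rows.append(
                {
                    "read_id": read_id,
                    "length": len(seq),
                    "aligned_length": core_len,
                    "n_edits": n_edits,
                    "cigar": cigar,
                    "percent_identity": 100.0 * (1.0 - n_edits / core_len),
                }
            )
    truth = pd.DataFrame(rows)
    truth.to_csv(f"{path}.truth.tsv", sep="\t", index=False)
    return path, truth


def _kmer_set(seq: str, k: int = 15) -> set[str]:
    from .decontam import reverse_complement

    both = seq + "#" + reverse_complement(seq)
    parts = both.split("#")
    kmers: set[str] = set()
    for s in parts:
        kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    return kmers


def make_contaminated_set(out_dir, n_clean: int, n_contaminant: int, error_rate: float = 0.05, read_length_range: tuple[int, int] = (300, 800), seed: int = 1) -> tuple[Path, Path, pd.DataFrame]:
    """FASTQ of clean + contaminant reads, the contaminant FASTA, and truth labels.

    Contaminant reads are substrings (with point substitutions at
    ``error_rate``) of a generated 10 kb stand-in genome; clean reads are
    verbatim substrings of an independent random genome regenerated until
    its 15-mer set (both strands) is disjoint from the stand-in's, which
    guarantees the built-in seed screen can make no false calls.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    contaminant = random_sequence(rng, 10_000)
    cont_kmers = _kmer_set(contaminant)
    while True:
        clean_genome = random_sequence(rng, 20_000)
        if not (cont_kmers & _kmer_set(clean_genome)):
            break

    fasta_path = out_dir / "contaminant_standin.fasta"
    with open(fasta_path, "w") as fh:
        fh.write(">contaminant_standin synthetic 10 kb control genome\n")
        for i in range(0, len(contaminant), 80):
            fh.write(contaminant[i : i + 80] + "\n")

    lo, hi = read_length_range
    reads = []
    for i in range(n_contaminant):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(contaminant) - length))
        core = np.array(list(contaminant[start : start + length]))
        err = rng.random(length) < error_rate
        if err.any():
            idx = np.searchsorted(BASES, core[err])
            core[err] = BASES[(idx + rng.integers(1, 4, size=int(err.sum()))) % 4]
        reads.append((f"cont_{i:05d}", "".join(core), True))
    for i in range(n_clean):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(clean_genome) - length))
        reads.append((f"clean_{i:05d}", clean_genome[start : start + length], False))
    order = rng.permutation(len(reads))

    fastq_path = out_dir / "contaminated.fastq"
    rows = []
    with open(fastq_path, "w") as fh:
        for j in order:
            read_id, seq, is_cont = reads[j]
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
            rows.append({"read_id": read_id, "is_contaminant": is_cont})
    truth = pd.DataFrame(rows)
    truth.to_csv(f"{fastq_path}.truth.tsv", sep="\t", index=False)
    return fastq_path, fasta_path, truth
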