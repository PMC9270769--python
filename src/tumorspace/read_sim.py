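"""Synthetic sequencing reads from per-sample genomes.

Two engines share one configuration:

* a built-in single/paired-end generator with a uniform per-base
  substitution error model, emitting FASTQ, a SAM with the true placements
  and an error-free SAM — enough to exercise a full variant-calling
  benchmark without external binaries;
* a thin subprocess wrapper around the ART read simulator
  (``art_illumina``) for platform-specific empirical error profiles.

Built-in quality strings are a constant Q30 symbol: the uniform error model
has no positional bias, so a flat profile is the honest description of it.
Realistic quality profiles are ART's job.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

__all__ = ["ReadSimConfig", "simulate_reads_builtin", "simulate_reads_art",
           "art_command"]

_COMP_TABLE = str.maketrans("ACGT", "TGCA")
_Q30 = chr(30 + 33)  # constant built-in base quality


def _revcomp(s: str) -> str:
    return s.translate(_COMP_TABLE)[::-1]


@dataclass
class ReadSimConfig:
    """Sequencing-experiment settings.

    mode : "single" or "paired".
    reads_per_cell : number of reads (single) or read pairs (paired) per
        sample; alternatively set ``coverage`` to derive the count from the
        genome length.
    read_length : bases per read.
    fragment_mean, fragment_sd : normal fragment-length model (paired mode);
        fragments are truncated to [read_length, genome length].
    error_rate : per-base substitution error probability (built-in engine).
    art_profile : ART sequencing-system code passed to ``-ss`` (e.g. "HS25"
        for Illumina HiSeq 2500).
    art_extra : custom passthrough string appended verbatim to the ART
        command line.
    """

    mode: str = "paired"
    reads_per_cell: int | None = 100
    coverage: float | None = None
    read_length: int = 100
    fragment_mean: float = 200.0
    fragment_sd: float = 10.0
    error_rate: float = 0.0
    art_profile: str = "HS25"
    art_extra: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("single", "paired"):
            raise ValueError(f"mode must be 'single' or 'paired', got {self.mode!r}")
        if self.reads_per_cell is None and self.coverage is None:
            raise ValueError("set reads_per_cell or coverage")
        if self.coverage is not None and self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.mode == "paired" and self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed the mean fragment size")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")

    def n_reads(self, genome_length: int) -> int:
        if self.reads_per_cell is not None:
            return int(self.reads_per_cell)
        per_read = self.read_length * (2 if self.mode == "paired" else 1)
        return max(1, int(round(self.coverage * genome_length / per_read)))


def _add_errors(read: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        base = chr(arr[i])
        arr[i] = ord(rng.choice([b for b in "ACGT" if b != base]))
    return arr.tobytes().decode()


def simulate_reads_builtin(
    genome: str,
    sample: str,
    cfg: ReadSimConfig,
    out_dir,
    rng: np.random.Generator | None = None,
) -> dict:
    """Generate FASTQ + truth SAM + error-free SAM for one sample genome.

    Fragment start positions are uniform over the genome; in paired mode the
    fragment length is round(Normal(mean, sd)) truncated to
    [read_length, genome length], mate 1 reads the fragment's 5' end forward
    and mate 2 its 3' end reverse-complemented.  Both SAMs carry the true
    1-based positions, proper mate flags and all-match CIGARs; the noisy SAM
    holds the error-bearing sequences, the ``*.truth.sam`` the error-free
    ones.

    Returns a dict of written paths (fastq1 [, fastq2], sam, truth_sam).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genome = genome.upper()
    L = len(genome)
    if L < cfg.read_length:
        raise ValueError(
            f"genome of sample {sample!r} (length {L}) is shorter than the "
            f"read length {cfg.read_length}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_name = f"sample_{sample}"
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": ref_name, "LN": L}]}
    n = cfg.n_reads(L)
    rl = cfg.read_length
    qual = _Q30 * rl

    paths = {
        "fastq1": out_dir / f"{ref_name}_R1.fastq",
        "sam": out_dir / f"{ref_name}.sam",
        "truth_sam": out_dir / f"{ref_name}.truth.sam",
    }
    if cfg.mode == "paired":
        paths["fastq2"] = out_dir / f"{ref_name}_R2.fastq"

    fq1 = open(paths["fastq1"], "w")
    fq2 = open(paths["fastq2"], "w") if cfg.mode == "paired" else None
    sam = pysam.AlignmentFile(str(paths["sam"]), "w", header=header)
    truth = pysam.AlignmentFile(str(paths["truth_sam"]), "w", header=header)

    def make_aln(name, seq, pos0, flag, mate_pos0=None, tlen=0):
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = seq
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos0
        a.mapping_quality = 60
        a.cigarstring = f"{len(seq)}M"
        if mate_pos0 is not None:
            a.next_reference_id = 0
            a.next_reference_start = mate_pos0
            a.template_length = tlen
        a.query_qualities = pysam.qualitystring_to_array(_Q30 * len(seq))
        return a

    try:
        for i in range(n):
            if cfg.mode == "single":
                start = int(rng.integers(0, L - rl + 1))
                clean = genome[start:start + rl]
                noisy = _add_errors(clean, cfg.error_rate, rng)
                name = f"{ref_name}_read{i}"
                fq1.write(f"@{name}\n{noisy}\n+\n{qual}\n")
                sam.write(make_aln(name, noisy, start, 0))
                truth.write(make_aln(name, clean, start, 0))
            else:
                frag = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
                frag = min(max(frag, rl), L)
                start = int(rng.integers(0, L - frag + 1))
                fragment = genome[start:start + frag]
                clean1 = fragment[:rl]
                clean2_fwd = fragment[-rl:]
                clean2 = _revcomp(clean2_fwd)
                noisy1 = _add_errors(clean1, cfg.error_rate, rng)
                noisy2 = _add_errors(clean2, cfg.error_rate, rng)
                name = f"{ref_name}_pair{i}"
                fq1.write(f"@{name}/1\n{noisy1}\n+\n{qual}\n")
                fq2.write(f"@{name}/2\n{noisy2}\n+\n{qual}\n")
                pos1 = start
                pos2 = start + frag - rl
                # 99/147: paired, proper, mate-reverse / reverse, first/second
                sam.write(make_aln(name, noisy1, pos1, 99, pos2, frag))
                sam.write(make_aln(name, _revcomp(noisy2), pos2, 147, pos1, -frag))
                truth.write(make_aln(name, clean1, pos1, 99, pos2, frag))
                truth.write(make_aln(name, clean2_fwd, pos2, 147, pos1, -frag))
    finally:
        fq1.close()
        if fq2 is not None:
            fq2.close()
        sam.close()
        truth.close()
    return paths


def art_command(fasta_path, cfg: ReadSimConfig, out_prefix) -> list:
    """Build the art_illumina command line for a sample genome."""
    cmd = ["art_illumina", "-ss", cfg.art_profile, "-sam",
           "-i", str(fasta_path), "-l", str(cfg.read_length),
           "-o", str(out_prefix)]
    if cfg.coverage is not None:
        cmd += ["-f", str(cfg.coverage)]
    else:
        cmd += ["-c", str(cfg.reads_per_cell)]
    if cfg.mode == "paired":
        cmd += ["-p", "-m", str(cfg.fragment_mean), "-s", str(cfg.fragment_sd)]
    if cfg.seed is not None:
        cmd += ["-rs", str(cfg.seed)]
    if cfg.art_extra:
        cmd += cfg.art_extra.split()
    return cmd


def simulate_reads_art(fasta_path, cfg: ReadSimConfig, out_dir) -> dict:
    """Run the external ART simulator on one sample FASTA.

    Raises RuntimeError (with the full command line) when the executable is
    missing, exits non-zero, or does not produce the expected outputs; in
    the missing-executable case the message points at the built-in
    simulator as the dependency-free alternative.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / Path(fasta_path).stem
    cmd = art_command(fasta_path, cfg, prefix)
    if shutil.which(cmd[0]) is None:
        raise RuntimeError(
            f"ART executable {cmd[0]!r} not found on PATH (command was: "
            f"{' '.join(cmd)}). Use simulate_reads_builtin for a "
            "dependency-free read simulation."
        )
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"ART failed with exit code {proc.returncode}: {' '.join(cmd)}\n"
            f"{proc.stderr}"
        )
    expected = [Path(f"{prefix}1.fq"), Path(f"{prefix}2.fq")] \
        if cfg.mode == "paired" else [Path(f"{prefix}.fq")]
    missing = [p for p in expected if not p.exists()]
    if missing:
        raise RuntimeError(
            f"ART finished but outputs are missing ({missing}): {' '.join(cmd)}"
        )
    outputs = {"fastq": [str(p) for p in expected]}
    for ext in (".sam", ".aln"):
        p = Path(f"{prefix}{ext}")
        if p.exists():
            outputs[ext.lstrip(".")] = str(p)
    return outputs
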