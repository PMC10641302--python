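"""Reading and writing haplotype datasets and result tables.

Datasets are written as one FASTA file per locus (headers
``sample{i}_allele{j}`` for diploid individuals) plus a TSV manifest, and
optionally in the ms-style text format (``//`` / ``segsites:`` /
``positions:`` blocks of 0/1 haplotype rows) for interoperability with
coalescent tooling.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalsim import HaplotypeDataset, SegPatterns
from .hky import BASES
from .sumstats import as_matrix

__all__ = [
    "write_pod_fasta",
    "read_pod_fasta",
    "write_ms",
    "read_ms",
    "write_profile_tsv",
]


def _decode(matrix: np.ndarray) -> list[str]:
    return ["".join(BASES[b] for b in row) for row in matrix]


def write_pod_fasta(pod: HaplotypeDataset, outdir: str | Path) -> Path:
    """Write one FASTA per locus plus ``manifest.tsv``; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for li, mat in enumerate(pod.loci):
        records = []
        for ai, seq in enumerate(_decode(mat)):
            sample, allele = divmod(ai, 2)
            records.append(
                SeqRecord(Seq(seq), id=f"sample{sample}_allele{allele}", description="")
            )
        fname = f"locus{li:04d}.fasta"
        SeqIO.write(records, outdir / fname, "fasta")
        rows.append({"locus": li, "length": mat.shape[1], "file": fname})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_pod_fasta(indir: str | Path) -> HaplotypeDataset:
    """Read a dataset written by :func:`write_pod_fasta` (or any per-locus
    FASTA directory with a ``manifest.tsv``)."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t")
    loci = []
    for _, row in manifest.iterrows():
        records = list(SeqIO.parse(indir / row["file"], "fasta"))
        loci.append(as_matrix([str(r.seq) for r in records]))
    return HaplotypeDataset(loci=loci)


def write_ms(patterns: Iterable[SegPatterns], handle) -> None:
    """Write loci in ms-style format; positions are uniform placeholders."""
    own = isinstance(handle, (str, Path))
    fh = open(handle, "w") if own else handle
    try:
        for pat in patterns:
            fh.write("\n//\n")
            fh.write(f"segsites: {pat.S}\n")
            if pat.S:
                pos = np.linspace(0, 1, pat.S + 2)[1:-1]
                fh.write("positions: " + " ".join(f"{p:.5f}" for p in pos) + "\n")
                for row in pat.to_matrix():
                    fh.write("".join(str(int(b)) for b in row) + "\n")
            else:
                fh.write("\n")
    finally:
        if own:
            fh.close()


def read_ms(handle, n_alleles: int | None = None) -> list[SegPatterns]:
    """Parse ms-style 0/1 blocks back into segregating-site patterns."""
    own = isinstance(handle, (str, Path))
    fh = open(handle) if own else handle
    try:
        text = fh.read()
    finally:
        if own:
            fh.close()
    out = []
    for block in text.split("//")[1:]:
        lines = [ln.strip() for ln in block.strip().splitlines() if ln.strip()]
        rows = [ln for ln in lines if set(ln) <= {"0", "1"} and not ln.startswith(("segsites", "positions"))]
        if not rows:
            segs = next((ln for ln in lines if ln.startswith("segsites:")), "segsites: 0")
            if int(segs.split()[1]) == 0 and n_alleles:
                out.append(SegPatterns(n=n_alleles, masks=np.zeros(0, dtype=np.uint64)))
                continue
        mat = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
        n = mat.shape[0]
        masks = np.zeros(mat.shape[1], dtype=np.uint64)
        for i in range(n):
            masks |= (mat[i].astype(np.uint64)) << np.uint64(i)
        out.append(SegPatterns(n=n, masks=masks))
    return out


def write_profile_tsv(prof, path: str | Path) -> None:
    """Per-locus statistic table plus a summary row of across-locus means."""
    per = prof.per_locus.copy()
    per.insert(0, "locus", np.arange(len(per)))
    cells = []
    for c in per.columns:
        v = "mean" if c == "locus" else prof.across_loci.get(c)
        cells.append("" if v is None else str(v))
    with open(path, "w") as fh:
        fh.write(per.to_csv(sep="\t", index=False))
        fh.write("\t".join(cells) + "\n")
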