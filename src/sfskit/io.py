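"""File formats: the genotype-likelihood TSV dialect, SAF dumps, SFS
files, call tables and a minimal VCF export.

GL TSV dialect
--------------
Comment lines start with ``#``.  The header line is

    #chrom  pos  anc  ind1  ...  indK

and each data row holds chrom, 1-based position, ancestral base (or ``.``
when unknown), then 10 natural-log genotype likelihoods per individual in
lexicographic genotype order (AA AC AG AT CC CG CT GG GT TT),
tab-separated.  Finite values round-trip to 6 decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gl import BASES, GENOTYPE_LABELS
from .saf import SAFTable

__all__ = [
    "GLTable",
    "read_gl_tsv",
    "write_gl_tsv",
    "write_saf_table",
    "read_saf_table",
    "write_sfs",
    "read_sfs",
    "write_truth",
    "read_truth",
    "write_vcf",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class GLTable:
    """Rectangular per-site × per-individual genotype-likelihood table."""

    chrom: list
    pos: np.ndarray  # 1-based
    ancestral: np.ndarray  # base index, -1 where unknown
    loglik: np.ndarray  # (S, k, 10) natural-log likelihoods
    individuals: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.loglik.shape[0]

    @property
    def k(self) -> int:
        return self.loglik.shape[1]

    def site_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]


def write_gl_tsv(table: GLTable, path) -> None:
    with open(path, "w") as fh:
        inds = table.individuals or [f"ind{i+1}" for i in range(table.k)]
        fh.write("#chrom\tpos\tanc\t" + "\t".join(inds) + "\n")
        fh.write("# 10 ln-likelihoods per individual, order: "
                 + " ".join(GENOTYPE_LABELS) + "\n")
        for s in range(table.n_sites):
            anc = "." if table.ancestral[s] < 0 else BASES[table.ancestral[s]]
            cells = [str(table.chrom[s]), str(int(table.pos[s])), anc]
            for d in range(table.k):
                cells.extend(f"{v:.6f}" for v in table.loglik[s, d])
            fh.write("\t".join(cells) + "\n")


def read_gl_tsv(path) -> GLTable:
    chrom: list = []
    pos: list = []
    anc: list = []
    rows: list = []
    individuals: list = []
    k = None
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line.lstrip("#").split("\t")
                if parts[:3] == ["chrom", "pos", "anc"]:
                    individuals = parts[3:]
                continue
            cells = line.split("\t")
            if k is None:
                if (len(cells) - 3) % 10 != 0 or len(cells) <= 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 + 10*k columns, "
                        f"got {len(cells)}"
                    )
                k = (len(cells) - 3) // 10
            if len(cells) != 3 + 10 * k:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(cells)} columns, "
                    f"expected {3 + 10 * k})"
                )
            key = (cells[0], cells[1])
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate site {key}")
            seen.add(key)
            if cells[2] != "." and cells[2] not in BASES:
                raise ParseError(
                    f"{path}:{lineno}: unknown ancestral base {cells[2]!r}"
                )
            try:
                p = int(cells[1])
                vals = [float(v) for v in cells[3:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            chrom.append(cells[0])
            pos.append(p)
            anc.append(-1 if cells[2] == "." else BASES.index(cells[2]))
            rows.append(vals)
    if k is None:
        return GLTable([], np.empty(0, int), np.empty(0, int),
                       np.empty((0, 0, 10)), individuals)
    loglik = np.asarray(rows).reshape(len(rows), k, 10)
    return GLTable(
        chrom, np.asarray(pos), np.asarray(anc), loglik,
        individuals or [f"ind{i+1}" for i in range(k)],
    )


def gl_table_from_sim(sim) -> GLTable:
    """Build a :class:`GLTable` from a :class:`~sfskit.simulate.SimData`."""
    S = sim.n_sites
    return GLTable(
        chrom=["sim"] * S,
        pos=np.arange(1, S + 1),
        ancestral=sim.ancestral.copy(),
        loglik=sim.gl,
        individuals=[f"ind{i+1}" for i in range(sim.k)],
    )


def write_saf_table(table: SAFTable, path) -> None:
    """One line per site: site_id, k, log_scale, then the per-category log
    likelihood values, tab-separated."""
    with open(path, "w") as fh:
        fh.write(f"#k={table.k}\tfolded={int(table.folded)}\n")
        ids = table.site_ids or list(range(table.n_sites))
        for i in range(table.n_sites):
            vals = "\t".join(f"{v:.6f}" for v in table.logvals[i])
            fh.write(f"{ids[i]}\t{table.k}\t{table.log_scale[i]:.6f}\t{vals}\n")


def read_saf_table(path) -> SAFTable:
    ids, scales, rows = [], [], []
    k = folded = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split("\t"):
                    key, _, val = tok.partition("=")
                    if key == "k":
                        k = int(val)
                    elif key == "folded":
                        folded = bool(int(val))
                continue
            cells = line.split("\t")
            try:
                ids.append(cells[0])
                row_k = int(cells[1])
                scales.append(float(cells[2]))
                rows.append([float(v) for v in cells[3:]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if k is None:
                k = row_k
            if row_k != k:
                raise ParseError(f"{path}:{lineno}: inconsistent k")
    if k is None:
        raise ParseError(f"{path}: empty SAF file")
    logvals = np.asarray(rows)
    if folded is None:
        folded = logvals.shape[1] == k + 1
    expected = k + 1 if folded else 2 * k + 1
    if logvals.shape[1] != expected:
        raise ParseError(f"{path}: expected {expected} categories per site")
    return SAFTable(logvals, np.asarray(scales), k, folded, ids)


def write_sfs(path, result) -> None:
    """Single whitespace-separated line of probabilities with a header
    comment recording k, folded flag, site count and final log-likelihood."""
    with open(path, "w") as fh:
        fh.write(
            f"# k={result.k} folded={int(result.folded)} "
            f"n_categories={len(result.probs)} loglik={result.loglik:.6f} "
            f"converged={int(result.converged)}\n"
        )
        fh.write(" ".join(f"{p:.10g}" for p in result.probs) + "\n")


def read_sfs(path):
    """Returns (probs, meta dict)."""
    meta: dict = {}
    probs = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    key, _, val = tok.partition("=")
                    if val:
                        meta[key] = val
                continue
            probs = np.array([float(v) for v in line.split()])
    if probs is None:
        raise ParseError(f"{path}: no SFS line found")
    return probs, meta


def write_truth(sim, path) -> None:
    df = pd.DataFrame(
        {
            "site_id": [f"sim:{i+1}" for i in range(sim.n_sites)],
            "is_variable": sim.is_variable.astype(int),
            "x": sim.popfreq,
            "anc": [BASES[a] for a in sim.ancestral],
            "der": [BASES[d] for d in sim.derived],
        }
    )
    for d in range(sim.k):
        df[f"g_ind{d+1}"] = sim.genotypes[:, d]
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(path, snp_table: pd.DataFrame, genotype_calls=None) -> None:
    """Minimal sites-only VCF export of called SNPs.

    ``snp_table`` needs columns site_id (chrom:pos), major, minor,
    p_not_variable, called.  QUAL is -10 log10(p_not_variable).  When
    ``genotype_calls`` (S, k) derived counts are given, GT fields are
    emitted.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        k = genotype_calls.shape[1] if genotype_calls is not None else 0
        if k:
            cols += "\tFORMAT" + "".join(f"\tind{i+1}" for i in range(k))
        fh.write(cols + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i, row in snp_table.reset_index(drop=True).iterrows():
            if not row["called"]:
                continue
            chrom, _, pos = str(row["site_id"]).partition(":")
            p0 = max(float(row["p_not_variable"]), 1e-300)
            qual = -10.0 * np.log10(p0)
            line = (
                f"{chrom}\t{pos}\t.\t{row['major']}\t{row['minor']}\t"
                f"{qual:.2f}\tPASS\t."
            )
            if k:
                line += "\tGT" + "".join(
                    f"\t{gt_map[int(g)]}" for g in genotype_calls[i]
                )
            fh.write(line + "\n")
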