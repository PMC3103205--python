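"""Readers and writers for the plain-text file dialects.

All files are whitespace-delimited with a header line where noted.
Round-trips are identities up to whitespace normalization; malformed
input raises :class:`FileFormatError` naming the file, line and rule.

Dialects
--------
pedigree   : header; columns id sire dam sex generation (0 = unknown parent)
genotypes  : no header; id then one 0/1/2/9 token per locus (9 = missing)
map        : header; columns chromosome snp_id position_bp (1-based)
phenotypes : header; columns id value ('NA' = missing)
phase      : no header; two rows per individual (paternal, maternal), id
             then 0/1 tokens (simulator truth output)
library    : no header; chromosome count haplotype-string per line
effects    : header with chain settings; columns locus_id effect effect_var
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .pedigree import Pedigree
from .phasing import HaplotypeLibrary
from .simulate import MISSING

__all__ = [
    "FileFormatError", "read_pedigree", "write_pedigree", "read_genotypes",
    "write_genotypes", "read_map", "write_map", "read_phenotypes",
    "write_phenotypes", "read_library", "write_library", "read_effects",
    "write_effects", "write_phase", "read_phase",
]


class FileFormatError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path, self.line_no = str(path), line_no


def _lines(path):
    with open(path) as fh:
        for no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line:
                yield no, line.split()


def read_pedigree(path) -> Pedigree:
    rows = []
    it = _lines(path)
    try:
        next(it)  # header
    except StopIteration:
        raise FileFormatError(path, 1, "empty pedigree file") from None
    for no, tok in it:
        if len(tok) != 5:
            raise FileFormatError(path, no, f"expected 5 columns, got {len(tok)}")
        try:
            rows.append((int(tok[0]), int(tok[1]), int(tok[2]), tok[3],
                         int(tok[4])))
        except ValueError as exc:
            raise FileFormatError(path, no, str(exc)) from None
        if tok[3] not in ("M", "F"):
            raise FileFormatError(path, no, f"sex must be M or F, got {tok[3]!r}")
    arr = list(zip(*rows))
    try:
        return Pedigree(np.array(arr[0]), np.array(arr[1]), np.array(arr[2]),
                        np.array(arr[3]), np.array(arr[4]))
    except ValueError as exc:
        raise FileFormatError(path, 0, f"pedigree validation failed: {exc}") from None


def write_pedigree(path, pedigree: Pedigree) -> None:
    pedigree.to_frame().to_csv(path, sep=" ", index=False)


def read_genotypes(path, ids: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Returns (ids, genotype matrix).  When ``ids`` is given, rows are
    checked and reordered to match it."""
    got_ids, rows = [], []
    width = None
    for no, tok in _lines(path):
        try:
            got_ids.append(int(tok[0]))
        except ValueError:
            raise FileFormatError(path, no, f"bad id {tok[0]!r}") from None
        vals = tok[1:]
        if width is None:
            width = len(vals)
        elif len(vals) != width:
            raise FileFormatError(path, no,
                                  f"expected {width} genotypes, got {len(vals)}")
        row = np.empty(len(vals), dtype=np.int8)
        for k, v in enumerate(vals):
            if v not in ("0", "1", "2", "9"):
                raise FileFormatError(path, no,
                                      f"genotype token {v!r} not in 0/1/2/9")
            row[k] = int(v)
        rows.append(row)
    got_ids = np.array(got_ids)
    G = np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.int8)
    if ids is not None:
        order = {g: k for k, g in enumerate(got_ids)}
        missing = [i for i in ids if int(i) not in order]
        if missing:
            raise FileFormatError(path, 0, f"no genotypes for ids {missing[:5]}")
        G = G[[order[int(i)] for i in ids]]
        got_ids = np.asarray(ids)
    return got_ids, G


def write_genotypes(path, ids: np.ndarray, genotypes: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i, row in zip(ids, genotypes):
            fh.write(f"{int(i)} " + " ".join(str(int(v)) for v in row) + "\n")


def read_map(path) -> GeneticMap:
    chroms, snp_ids, pos = [], [], []
    it = _lines(path)
    try:
        next(it)
    except StopIteration:
        raise FileFormatError(path, 1, "empty map file") from None
    for no, tok in it:
        if len(tok) != 3:
            raise FileFormatError(path, no, f"expected 3 columns, got {len(tok)}")
        try:
            chroms.append(int(tok[0]))
            snp_ids.append(tok[1])
            pos.append(int(tok[2]))
        except ValueError as exc:
            raise FileFormatError(path, no, str(exc)) from None
    try:
        return GeneticMap(np.array(chroms), np.array(pos), np.array(snp_ids))
    except ValueError as exc:
        raise FileFormatError(path, 0, f"map validation failed: {exc}") from None


def write_map(path, gmap: GeneticMap) -> None:
    pd.DataFrame({"chromosome": gmap.chrom, "snp_id": gmap.snp_id,
                  "position_bp": gmap.pos}).to_csv(path, sep=" ", index=False)


def read_phenotypes(path, ids: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    got_ids, vals = [], []
    it = _lines(path)
    try:
        next(it)
    except StopIteration:
        raise FileFormatError(path, 1, "empty phenotype file") from None
    for no, tok in it:
        if len(tok) != 2:
            raise FileFormatError(path, no, f"expected 2 columns, got {len(tok)}")
        try:
            got_ids.append(int(tok[0]))
            vals.append(float("nan") if tok[1] == "NA" else float(tok[1]))
        except ValueError as exc:
            raise FileFormatError(path, no, str(exc)) from None
    got_ids = np.array(got_ids)
    vals = np.array(vals)
    if ids is not None:
        order = {g: k for k, g in enumerate(got_ids)}
        out = np.full(len(ids), np.nan)
        for k, i in enumerate(ids):
            if int(i) in order:
                out[k] = vals[order[int(i)]]
        return np.asarray(ids), out
    return got_ids, vals


def write_phenotypes(path, ids: np.ndarray, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("id value\n")
        for i, v in zip(ids, values):
            fh.write(f"{int(i)} {'NA' if np.isnan(v) else repr(float(v))}\n")


def write_phase(path, ids: np.ndarray, paternal: np.ndarray,
                maternal: np.ndarray) -> None:
    with open(path, "w") as fh:
        for k, i in enumerate(ids):
            for hap in (paternal[k], maternal[k]):
                fh.write(f"{int(i)} " + " ".join(str(int(v)) for v in hap) + "\n")


def read_phase(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids, rows = [], []
    for no, tok in _lines(path):
        ids.append(int(tok[0]))
        rows.append(np.array([int(v) for v in tok[1:]], dtype=np.int8))
    if len(rows) % 2:
        raise FileFormatError(path, 0, "odd number of haplotype rows")
    ids = np.array(ids[::2])
    pat = np.vstack(rows[::2])
    mat = np.vstack(rows[1::2])
    return ids, pat, mat


def write_library(path, library: HaplotypeLibrary) -> None:
    with open(path, "w") as fh:
        for c in library.chromosomes:
            for hap, count in zip(library.haplotypes[c], library.counts[c]):
                fh.write(f"{c} {int(count)} " + "".join(map(str, hap)) + "\n")


def read_library(path) -> HaplotypeLibrary:
    seqs: dict[int, list] = {}
    counts: dict[int, list] = {}
    for no, tok in _lines(path):
        if len(tok) != 3:
            raise FileFormatError(path, no, f"expected 3 columns, got {len(tok)}")
        try:
            c, count = int(tok[0]), int(tok[1])
            hap = np.array([int(ch) for ch in tok[2]], dtype=np.int8)
        except ValueError as exc:
            raise FileFormatError(path, no, str(exc)) from None
        if np.any((hap < 0) | (hap > 1)):
            raise FileFormatError(path, no, "haplotype alleles must be 0/1")
        seqs.setdefault(c, []).append(hap)
        counts.setdefault(c, []).append(count)
    lib = HaplotypeLibrary()
    for c in seqs:
        lib.haplotypes[c] = np.vstack(seqs[c])
        lib.counts[c] = np.array(counts[c], dtype=np.int64)
    return lib


def write_effects(path, effects: np.ndarray, effect_vars: np.ndarray,
                  intercept: float, settings: dict | None = None) -> None:
    with open(path, "w") as fh:
        meta = " ".join(f"{k}={v}" for k, v in (settings or {}).items())
        fh.write(f"# intercept={float(intercept)!r} {meta}\n")
        fh.write("locus effect effect_var\n")
        for j, (e, v) in enumerate(zip(effects, effect_vars)):
            fh.write(f"{j} {float(e)!r} {float(v)!r}\n")


def read_effects(path) -> tuple[np.ndarray, np.ndarray, float]:
    effects, evars = [], []
    intercept = 0.0
    with open(path) as fh:
        for no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].split():
                    if part.startswith("intercept="):
                        intercept = float(part.split("=", 1)[1])
                continue
            tok = line.split()
            if tok[0] == "locus":
                continue
            if len(tok) != 3:
                raise FileFormatError(path, no, f"expected 3 columns, got {len(tok)}")
            effects.append(float(tok[1]))
            evars.append(float(tok[2]))
    return np.array(effects), np.array(evars), intercept
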