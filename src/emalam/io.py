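"""Readers and writers for admixture-estimate file dialects.

Supported formats:

* ADMIXTURE ``.Q`` — whitespace-delimited, one row per individual, K
  columns of ancestry fractions.
* ADMIXTURE ``.P`` — one row per SNP, K columns holding the frequency of
  the *first* allele in each population (the second allele's frequency is
  the complement).
* STRUCTURE output files — the ``Inferred ancestry of individuals`` block
  and the ``Estimated Allele Frequencies in each cluster`` block of the
  plain-text outfile; multi-allelic loci are supported.
* genotype tables — N x M whitespace-delimited integers in {0, 1, 2}
  counting copies of the first allele at bi-allelic markers.

File input is validated with a loose simplex tolerance because these tools
print few decimals; rows are renormalized on read.  Writers print six
decimals, and read(write(x)) reproduces x to that precision.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import AdmixEstimate, GenotypeMatrix, ValidationError, validate_estimate

__all__ = [
    "RunBundle",
    "read_admixture_q",
    "read_admixture_p",
    "read_structure_output",
    "read_genotypes",
    "write_estimate",
    "write_genotypes",
]

#: renormalization slack for parsed matrices (ADMIXTURE prints 6 decimals,
#: STRUCTURE often 3)
READ_TOL = 1e-3
_PRINT_FMT = "%.6f"


@dataclass(frozen=True)
class RunBundle:
    """An estimate plus file-level metadata."""

    estimate: AdmixEstimate
    labels: tuple[str, ...] | None = None
    pop_names: tuple[str, ...] | None = None
    source: str = "other"

    def __post_init__(self):
        if self.labels is not None and len(self.labels) != self.estimate.N:
            raise ValidationError(
                f"{len(self.labels)} labels for {self.estimate.N} individuals"
            )


def _read_numeric_table(path, what: str) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                raise ValidationError(f"{what}, line {lineno}: non-numeric token ({exc})")
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValidationError(
                    f"{what}, line {lineno}: expected {width} columns, got {len(row)}"
                )
            rows.append(row)
    if not rows:
        raise ValidationError(f"{what}: file is empty")
    return np.array(rows)


def read_admixture_q(path, tol: float = READ_TOL) -> np.ndarray:
    """Read an ADMIXTURE-style .Q file into an (N, K) matrix.

    Rows whose sum deviates from 1 by at most ``tol`` are renormalized;
    larger deviations are rejected.
    """
    Q = _read_numeric_table(path, f".Q file {path}")
    if Q.min() < -tol or Q.max() > 1 + tol:
        raise ValidationError(f".Q file {path}: entries outside [0, 1]")
    sums = Q.sum(axis=1)
    if np.any(np.abs(sums - 1) > tol):
        bad = int(np.argmax(np.abs(sums - 1)))
        raise ValidationError(
            f".Q file {path}: row {bad + 1} sums to {sums[bad]:.6g}"
        )
    Q = np.clip(Q, 0.0, 1.0)
    return Q / Q.sum(axis=1, keepdims=True)


def read_admixture_p(path, K: int, tol: float = READ_TOL) -> tuple[np.ndarray, ...]:
    """Read an ADMIXTURE-style .P file (M rows x K columns) into P blocks.

    Column k holds the first-allele frequency in population k; the returned
    blocks are (K, 2) with the complement filled in.
    """
    tbl = _read_numeric_table(path, f".P file {path}")
    if tbl.shape[1] != K:
        raise ValidationError(
            f".P file {path}: {tbl.shape[1]} columns, expected K={K}"
        )
    if tbl.min() < -tol or tbl.max() > 1 + tol:
        raise ValidationError(f".P file {path}: frequencies outside [0, 1]")
    tbl = np.clip(tbl, 0.0, 1.0)
    return tuple(np.stack([tbl[m], 1.0 - tbl[m]], axis=1) for m in range(tbl.shape[0]))


_ANCESTRY_HEADER = re.compile(r"Inferred ancestry of individuals", re.IGNORECASE)
_FREQ_HEADER = re.compile(r"Estimated Allele Frequencies in each cluster", re.IGNORECASE)
_LOCUS_LINE = re.compile(r"^Locus\s+\d+")


def read_structure_output(path) -> RunBundle:
    """Parse Q, P and individual labels from a STRUCTURE output file.

    Recognizes the ancestry block (lines like
    ``1  ind1  (0)  1 :  0.700 0.300``, K fractions after the colon) and
    the cluster allele-frequency block (per locus, one line per allele:
    allele id, overall frequency in parentheses, then K cluster
    frequencies).  Tolerant to column-width changes; fails loudly if either
    block is missing or the two blocks disagree on K.
    """
    text = Path(path).read_text().splitlines()
    q_rows, labels = [], []
    p_blocks: list[list[list[float]]] = []
    i = 0
    n_lines = len(text)
    found_anc = found_freq = False

    while i < n_lines:
        line = text[i]
        if _ANCESTRY_HEADER.search(line):
            found_anc = True
            i += 1
            while i < n_lines:
                s = text[i].strip()
                if not s:
                    if q_rows:
                        break
                    i += 1
                    continue
                if ":" in s and not s.lower().startswith("label"):
                    left, _, right = s.partition(":")
                    try:
                        fracs = [float(t) for t in right.split()]
                    except ValueError:
                        break
                    if fracs:
                        q_rows.append(fracs)
                        ltoks = left.split()
                        labels.append(ltoks[1] if len(ltoks) > 1 else ltoks[0])
                elif q_rows:
                    break
                i += 1
            continue
        if _FREQ_HEADER.search(line):
            found_freq = True
            i += 1
            current: list[list[float]] | None = None
            while i < n_lines:
                s = text[i].strip()
                if _LOCUS_LINE.match(s):
                    if current:
                        p_blocks.append(current)
                    current = []
                elif current is not None and s:
                    toks = s.replace("(", " ").replace(")", " ").split()
                    vals = []
                    for t in toks:
                        try:
                            vals.append(float(t))
                        except ValueError:
                            vals = []
                            break
                    # allele line: allele id, overall freq, K cluster freqs
                    if len(vals) >= 3 and float(vals[0]).is_integer():
                        current.append(vals[2:])
                i += 1
            if current:
                p_blocks.append(current)
            continue
        i += 1

    if not found_anc or not q_rows:
        raise ValidationError(f"{path}: no 'Inferred ancestry of individuals' block found")
    if not found_freq or not p_blocks:
        raise ValidationError(f"{path}: no allele-frequency block found")

    K = len(q_rows[0])
    if any(len(r) != K for r in q_rows):
        raise ValidationError(f"{path}: ragged ancestry rows")
    for m, blk in enumerate(p_blocks):
        if any(len(a) != K for a in blk):
            raise ValidationError(
                f"{path}: locus {m + 1} frequency lines disagree with K={K} "
                "from the ancestry block"
            )
    Q = np.array(q_rows)
    P = tuple(np.array(blk).T for blk in p_blocks)  # (K, J_m)
    est = validate_estimate(Q, P, tol=READ_TOL)
    return RunBundle(estimate=est, labels=tuple(labels), source="structure")


def read_genotypes(path) -> GenotypeMatrix:
    """Read an N x M table of first-allele counts (0/1/2) as genotypes."""
    tbl = _read_numeric_table(path, f"genotype file {path}")
    if not np.all(np.isin(tbl, (0.0, 1.0, 2.0))):
        raise ValidationError(f"genotype file {path}: entries must be 0, 1 or 2")
    counts = tbl.astype(np.int64)
    blocks = tuple(
        np.stack([counts[:, m], 2 - counts[:, m]], axis=1)
        for m in range(counts.shape[1])
    )
    return GenotypeMatrix(X=blocks)


def write_genotypes(x: GenotypeMatrix, path) -> None:
    """Write bi-allelic genotypes as an N x M table of first-allele counts."""
    cols = []
    for blk in x.X:
        if blk.shape[1] != 2:
            raise ValueError("genotype table output requires bi-allelic markers")
        cols.append(blk[:, 0])
    np.savetxt(path, np.stack(cols, axis=1), fmt="%d")


def write_estimate(bundle: RunBundle, prefix, extra: dict | None = None) -> dict[str, str]:
    """Write ``<prefix>.Q``, ``<prefix>.P`` and a ``<prefix>.json`` sidecar.

    The .P file uses the ADMIXTURE layout (bi-allelic only: first-allele
    frequency per SNP and population); for multi-allelic estimates the full
    frequency blocks go into the sidecar instead.  ``extra`` is merged into
    the sidecar, e.g. interval bounds or optimization metadata.  Returns the
    mapping of artifact name to path.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    est = bundle.estimate
    out = {}
    qpath = prefix.with_suffix(".Q")
    np.savetxt(qpath, est.Q, fmt=_PRINT_FMT)
    out["Q"] = str(qpath)
    sidecar = {
        "N": est.N,
        "M": est.M,
        "K": est.K,
        "source": bundle.source,
        "biallelic": est.is_biallelic,
    }
    if bundle.labels is not None:
        sidecar["labels"] = list(bundle.labels)
    if bundle.pop_names is not None:
        sidecar["pop_names"] = list(bundle.pop_names)
    if est.is_biallelic:
        ppath = prefix.with_suffix(".P")
        P1 = np.stack([blk[:, 0] for blk in est.P], axis=0)  # (M, K)
        np.savetxt(ppath, P1, fmt=_PRINT_FMT)
        out["P"] = str(ppath)
    else:
        sidecar["P_blocks"] = [blk.tolist() for blk in est.P]
    if extra:
        sidecar.update(extra)
    jpath = prefix.with_suffix(".json")
    jpath.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    out["json"] = str(jpath)
    return out
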