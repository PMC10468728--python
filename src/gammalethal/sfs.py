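"""Unfolded site frequency spectra: construction, p_lth scaling, file I/O.

The unfolded SFS of a sample of ``n`` haplotypes is the vector of counts
of polymorphic sites at which the derived allele is carried by exactly
``i`` haplotypes, for ``i = 1 .. n-1``.  Sites fixed in the sample
(``i = n``) or absent (``i = 0``) never enter the spectrum.

The "gamma + lethal" correction assumes a proportion ``p_lth`` of new
mutations are so deleterious that they can never appear in a sample;
operationally every entry of the *selected* SFS is multiplied by
``1 - p_lth`` (the neutral SFS is never scaled).  Scaled entries are
kept fractional: rounding would add un-modelled noise, and the
downstream Poisson likelihood accepts non-integer counts.

Datasets are stored in a small text dialect modelled on the input
convention of SFS-based DFE inference tools: a header line
``<#neutral> <#selected> <n>`` followed by one line per SFS holding the
``n-1`` entries and the assumed sequence length, neutral spectra first.
A file may contain several such blocks, one per species, optionally
preceded by a ``# species: <label>`` comment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SFS",
    "SFSDataset",
    "build_unfolded_sfs",
    "sfs_from_derived_counts",
    "scale_sfs",
    "read_dataset",
    "write_dataset",
    "sfs_dispersion",
]

DEFAULT_LENGTH = 20000.0


@dataclass(frozen=True)
class SFS:
    """An unfolded site frequency spectrum.

    counts[i-1] is the (possibly fractional, after p_lth scaling) number
    of sites with derived-allele count i among n haplotypes.
    """

    counts: np.ndarray
    n: int
    length: float = DEFAULT_LENGTH
    kind: str = "neutral"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if counts.shape != (self.n - 1,):
            raise ValueError(
                f"counts must have length n-1 = {self.n - 1}, got {counts.shape}"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("SFS counts must be finite and non-negative")
        if self.kind not in ("neutral", "selected"):
            raise ValueError("kind must be 'neutral' or 'selected'")

    @property
    def n_segregating(self) -> float:
        return float(self.counts.sum())


@dataclass
class SFSDataset:
    """Matched neutral/selected SFS pairs, optionally from several species."""

    pairs: list[tuple[SFS, SFS]]
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("dataset must contain at least one SFS pair")
        n = self.pairs[0][0].n
        for neu, sel in self.pairs:
            if neu.n != n or sel.n != n:
                raise ValueError("all SFS in a dataset must share the sample size n")
            if neu.kind != "neutral" or sel.kind != "selected":
                raise ValueError("each pair must be (neutral, selected)")
        if not self.species:
            self.species = ["species_1"] * len(self.pairs)
        if len(self.species) != len(self.pairs):
            raise ValueError("species labels must match the number of pairs")

    @property
    def n(self) -> int:
        return self.pairs[0][0].n

    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s)
        return list(seen)

    def pairs_for(self, species: str) -> list[tuple[SFS, SFS]]:
        return [p for p, s in zip(self.pairs, self.species) if s == species]


def _positions(hap) -> np.ndarray:
    """Accept either a bare position array or a Haplotype-like object."""
    pos = getattr(hap, "positions", hap)
    return np.asarray(pos, dtype=float)


def build_unfolded_sfs(
    haplotypes: Sequence, n: int, length: float = DEFAULT_LENGTH,
    kind: str = "neutral",
) -> SFS:
    """Tabulate the unfolded SFS of a complete sample of n haplotypes.

    The derived state is mutation presence (the ancestral state is known
    by construction in the infinite-sites simulator).  Sites carried by
    all n haplotypes are fixed in the sample and excluded.
    """
    if len(haplotypes) != n:
        raise ValueError(f"expected exactly n = {n} haplotypes, got {len(haplotypes)}")
    counts = np.zeros(n - 1)
    all_pos = [_positions(h) for h in haplotypes]
    if any(p.size for p in all_pos):
        pooled = np.concatenate([p for p in all_pos if p.size])
        _, carriers = np.unique(pooled, return_counts=True)
        seg = carriers[(carriers >= 1) & (carriers <= n - 1)]
        counts = np.bincount(seg, minlength=n)[1:n].astype(float)
    return SFS(counts=counts, n=n, length=length, kind=kind)


def sfs_from_derived_counts(
    derived: Iterable[int], n: int, length: float = DEFAULT_LENGTH,
    kind: str = "neutral",
) -> SFS:
    """Build an SFS from per-site derived-allele counts (tabular samples)."""
    derived = np.asarray(list(derived), dtype=int)
    seg = derived[(derived >= 1) & (derived <= n - 1)]
    counts = np.bincount(seg, minlength=n)[1:n].astype(float)
    return SFS(counts=counts, n=n, length=length, kind=kind)


def scale_sfs(sfs: SFS, p_lth: float) -> SFS:
    """Apply the gamma + lethal scaling: multiply every entry by 1 - p_lth.

    Only selected spectra may be scaled; entries stay fractional.
    """
    if sfs.kind != "selected":
        raise ValueError("only the selected SFS is ever scaled by 1 - p_lth")
    if not 0.0 <= p_lth <= 1.0:
        raise ValueError("p_lth must lie in [0, 1]")
    return replace(sfs, counts=sfs.counts * (1.0 - p_lth))


class SFSParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def write_dataset(ds: SFSDataset, path) -> None:
    path = Path(path)
    lines: list[str] = []
    for species in ds.species_names():
        pairs = ds.pairs_for(species)
        n = ds.n
        lines.append(f"# species: {species}")
        lines.append(f"{len(pairs)} {len(pairs)} {n}")
        for neu, _ in pairs:
            lines.append(" ".join(f"{c:.10g}" for c in neu.counts) + f" {neu.length:.10g}")
        for _, sel in pairs:
            lines.append(" ".join(f"{c:.10g}" for c in sel.counts) + f" {sel.length:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_dataset(path) -> SFSDataset:
    path = Path(path)
    pairs: list[tuple[SFS, SFS]] = []
    species: list[str] = []
    pending_label: str | None = None
    block = 0
    lines = path.read_text().splitlines()
    idx = 0

    def parse_sfs_line(lineno: int, n: int, kind: str) -> SFS:
        parts = lines[lineno - 1].split()
        if len(parts) != n:
            raise SFSParseError(
                path, lineno,
                f"expected {n - 1} SFS entries plus a length ({n} fields), "
                f"got {len(parts)}",
            )
        try:
            values = [float(v) for v in parts]
        except ValueError as exc:
            raise SFSParseError(path, lineno, f"non-numeric field: {exc}") from None
        return SFS(np.asarray(values[:-1]), n=n, length=values[-1], kind=kind)

    while idx < len(lines):
        line = lines[idx].strip()
        if not line:
            idx += 1
            continue
        if line.startswith("#"):
            if "species:" in line:
                pending_label = line.split("species:", 1)[1].strip()
            idx += 1
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SFSParseError(path, idx + 1, "expected header '<#neutral> <#selected> <n>'")
        try:
            k_neu, k_sel, n = (int(p) for p in parts)
        except ValueError:
            raise SFSParseError(path, idx + 1, "header fields must be integers") from None
        if k_neu != k_sel:
            raise SFSParseError(path, idx + 1, "neutral and selected SFS counts must match")
        block += 1
        label = pending_label or f"species_{block}"
        pending_label = None
        idx += 1
        if idx + 2 * k_neu > len(lines):
            raise SFSParseError(path, len(lines), "truncated SFS block")
        neutrals = [parse_sfs_line(idx + j + 1, n, "neutral") for j in range(k_neu)]
        idx += k_neu
        selected = [parse_sfs_line(idx + j + 1, n, "selected") for j in range(k_sel)]
        idx += k_sel
        pairs.extend(zip(neutrals, selected))
        species.extend([label] * k_neu)
    if not pairs:
        raise SFSParseError(path, 1, "no SFS blocks found")
    return SFSDataset(pairs=pairs, species=species)


def sfs_dispersion(datasets: Sequence[SFSDataset], kind: str = "selected") -> pd.DataFrame:
    """Across-species per-entry dispersion of mean SFS counts.

    For each entry index i, the mean of each dataset's average counts is
    taken per dataset ("species"), then the mean and standard deviation
    across species are reported.  Demonstrates the homogenisation
    mechanism of p_lth: scaling all entries by ``1 - p_lth`` shrinks the
    absolute between-species spread by exactly that factor.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to measure dispersion")
    n = datasets[0].n
    which = 0 if kind == "neutral" else 1
    per_species = []
    for ds in datasets:
        if ds.n != n:
            raise ValueError("all datasets must share the sample size n")
        per_species.append(np.mean([p[which].counts for p in ds.pairs], axis=0))
    per_species = np.asarray(per_species)
    return pd.DataFrame(
        {
            "entry": np.arange(1, n),
            "mean": per_species.mean(axis=0),
            "sd": per_species.std(axis=0, ddof=1),
        }
    )
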