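"""Reading and writing GENEPOP genotype files and phenotype tables.

The GENEPOP text format is the lingua franca of microsatellite population
genetics: a title line, one locus name per line (or a single comma-separated
line), then population blocks introduced by a line reading ``pop`` and
containing one ``individual_id ,  gggggg gggggg ...`` record per diploid.
Allele codes are 2- or 3-digit positive integers; ``00``/``000`` encodes a
missing allele, and a call with any missing allele is treated as a missing
diploid call (GENEPOP semantics: missingness is a property of the whole call).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "GenepopParseError",
    "PhenotypeSchemaError",
    "read_genepop",
    "write_genepop",
    "read_phenotypes",
    "write_phenotypes",
]

#: Factor levels for the depth factors of the transplant designs.
DEPTH_LEVELS = ("shallow", "mesophotic")
TRAIT_NAMES = ("growth_mm", "necrosis_pct")

REQUIRED_PHENOTYPE_COLUMNS = (
    "individual",
    "sample",
    "origin_depth",
    "treatment_depth",
    "trait",
    "value",
)


class GenepopParseError(ValueError):
    """Raised when a GENEPOP file is malformed; carries the offending line number."""


class PhenotypeSchemaError(ValueError):
    """Raised when a phenotype table violates the declared schema."""


@dataclass
class GenotypeMatrix:
    """Diploid codominant genotypes for a set of individuals at a set of loci.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; allele codes are
    positive integers and 0 marks a missing allele.  A call is missing iff
    either allele is 0 (no half-missing calls).
    """

    individuals: list[str]
    loci: list[str]
    populations: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci x 2"
            )
        if len(self.populations) != n:
            raise ValueError("one population label required per individual")
        # normalise half-missing calls to fully missing
        half = (self.calls == 0).any(axis=2) & (self.calls != 0).any(axis=2)
        if half.any():
            self.calls[half] = 0

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing diploid calls."""
        return (self.calls == 0).any(axis=2)

    def sample_index(self, sample: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.populations) if p == sample])
        if idx.size == 0:
            raise KeyError(f"unknown sample {sample!r}")
        return idx

    def subset(self, samples: Sequence[str] | None = None,
               loci: Sequence[str] | None = None) -> "GenotypeMatrix":
        samples = list(samples) if samples is not None else self.sample_names
        loci = list(loci) if loci is not None else self.loci
        ridx = [i for i, p in enumerate(self.populations) if p in set(samples)]
        cidx = [self.loci.index(l) for l in loci]
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in ridx],
            loci=loci,
            populations=[self.populations[i] for i in ridx],
            calls=self.calls[np.ix_(ridx, cidx)].copy(),
        )

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def allele_counts(self, locus: str | int, sample: str | None = None) -> dict[int, int]:
        """Counts of each allele code at a locus (over non-missing calls)."""
        j = locus if isinstance(locus, int) else self.locus_index(locus)
        calls = self.calls[:, j, :]
        if sample is not None:
            calls = calls[self.sample_index(sample)]
        keep = (calls != 0).all(axis=1)
        vals, cnts = np.unique(calls[keep].ravel(), return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))

    def allele_frequencies(self, locus: str | int, sample: str | None = None) -> dict[int, float]:
        counts = self.allele_counts(locus, sample)
        tot = sum(counts.values())
        return {a: c / tot for a, c in counts.items()} if tot else {}


# ---------------------------------------------------------------------------
# GENEPOP parsing


_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _detect_allele_digits(token: str) -> int:
    if len(token) in (4, 6) and token.isdigit():
        return len(token) // 2
    raise ValueError(f"cannot infer allele digits from genotype field {token!r}")


def read_genepop(path: str | Path, allele_digits: int | None = None) -> GenotypeMatrix:
    """Parse a GENEPOP file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        Path to the GENEPOP text file.
    allele_digits
        2 or 3; ``None`` auto-detects from the width of the first genotype
        field (4 characters -> 2-digit alleles, 6 -> 3-digit).
    """
    if allele_digits not in (None, 2, 3):
        raise ValueError("allele_digits must be 2, 3 or None (auto)")
    text = Path(path).read_text()
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    # drop trailing blank lines but keep line numbers for diagnostics
    numbered = [(i + 1, ln.rstrip()) for i, ln in enumerate(lines)]
    while numbered and not numbered[-1][1].strip():
        numbered.pop()
    if len(numbered) < 3:
        raise GenepopParseError("empty GENEPOP file: need title, loci and at least one pop")

    it = iter(numbered)
    next(it)  # title line, content ignored

    loci: list[str] = []
    first_pop_line = None
    for lineno, ln in it:
        if _POP_RE.match(ln):
            first_pop_line = lineno
            break
        for name in ln.split(","):
            name = name.strip()
            if name:
                loci.append(name)
    if first_pop_line is None:
        raise GenepopParseError("no 'pop' line found")
    if not loci:
        raise GenepopParseError("zero loci declared before the first 'pop' line")

    individuals: list[str] = []
    block_of: list[int] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0

    for lineno, ln in it:
        if _POP_RE.match(ln):
            pop_counter += 1
            continue
        if not ln.strip():
            continue
        if pop_counter == 0:
            pop_counter = 1
        if "," not in ln:
            raise GenepopParseError(
                f"line {lineno}: expected 'id , genotypes' record (no comma found)"
            )
        ind_id, geno_part = ln.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {lineno}: {len(tokens)} genotype fields for {len(loci)} loci"
            )
        nonlocal_digits = allele_digits
        if nonlocal_digits is None:
            try:
                nonlocal_digits = _detect_allele_digits(tokens[0])
            except ValueError:
                raise GenepopParseError(
                    f"line {lineno}: malformed genotype field {tokens[0]!r} "
                    "(expected 4 or 6 digits)"
                ) from None
            allele_digits = nonlocal_digits
        width = 2 * nonlocal_digits
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) != width or not tok.isdigit():
                raise GenepopParseError(
                    f"line {lineno}: malformed genotype field {tok!r} "
                    f"(expected {width} digits)"
                )
            a = int(tok[:nonlocal_digits])
            b = int(tok[nonlocal_digits:])
            if a == 0 or b == 0:
                a = b = 0
            row.append((a, b))
        individuals.append(ind_id)
        block_of.append(pop_counter)
        rows.append(row)

    if not rows:
        raise GenepopParseError("zero individuals in file")
    # population label per block: longest common prefix of the block's ids
    # (the usual GENEPOP convention of ids encoding the sample name),
    # stripped of separator tail; falls back to the first id, then "popK".
    import os.path
    populations: list[str] = []
    for k in sorted(set(block_of)):
        ids = [individuals[i] for i, b in enumerate(block_of) if b == k]
        if len(set(ids)) == 1:
            label = ids[0]
        else:
            prefix = os.path.commonprefix(ids)
            cut = max(prefix.rfind(s) for s in "_-.")
            if cut > 0:
                prefix = prefix[:cut]
            label = prefix
        label = label or (ids[0] or f"pop{k}")
        populations.extend([label] * len(ids))
    calls = np.array(rows, dtype=np.int32)
    return GenotypeMatrix(individuals, loci, populations, calls)


def write_genepop(geno: GenotypeMatrix, path: str | Path,
                  allele_digits: int | None = None, title: str = "margin-adapt export") -> None:
    """Write a :class:`GenotypeMatrix` as a GENEPOP file (lossless round-trip)."""
    if allele_digits is None:
        allele_digits = 3 if geno.calls.max(initial=0) > 99 else 2
    if geno.calls.max(initial=0) >= 10 ** allele_digits:
        raise ValueError("allele codes exceed the chosen digit width")
    out = [title]
    out.extend(geno.loci)
    fmt = f"0{allele_digits}d"
    pops = geno.populations
    prev = None
    for i, ind in enumerate(geno.individuals):
        if pops[i] != prev:
            out.append("pop")
            prev = pops[i]
        fields = " ".join(
            f"{a:{fmt}}{b:{fmt}}" for a, b in geno.calls[i]
        )
        out.append(f"{ind} , {fields}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Phenotype tables


@dataclass
class PhenotypeTable:
    """Colony-level trait records for the transplant / common-garden designs.

    One row per (individual, trait, time point).  ``origin_depth`` and
    ``treatment_depth`` are the two crossed fixed factors; ``time`` is optional
    (absent for single-measurement traits such as linear growth).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise PhenotypeSchemaError(f"missing required column(s): {missing}")
        if "time" not in df.columns:
            df["time"] = 0
        try:
            df["value"] = pd.to_numeric(df["value"], errors="raise")
        except (ValueError, TypeError) as e:
            raise PhenotypeSchemaError(f"non-numeric trait value: {e}") from e
        if not np.isfinite(df["value"]).all():
            raise PhenotypeSchemaError("trait values must be finite")
        for col in ("origin_depth", "treatment_depth"):
            bad = set(df[col].unique()) - set(DEPTH_LEVELS)
            if bad:
                raise PhenotypeSchemaError(
                    f"unknown {col} level(s) {sorted(bad)}; expected {DEPTH_LEVELS}"
                )
        bad_traits = set(df["trait"].unique()) - set(TRAIT_NAMES)
        if bad_traits:
            raise PhenotypeSchemaError(
                f"unknown trait(s) {sorted(bad_traits)}; expected {TRAIT_NAMES}"
            )
        nec = df.loc[df["trait"] == "necrosis_pct", "value"]
        if ((nec < 0) | (nec > 100)).any():
            raise PhenotypeSchemaError("necrosis_pct values must lie in [0, 100]")
        dup = df.duplicated(subset=["individual", "trait", "time"])
        if dup.any():
            first = df[dup].iloc[0]
            raise PhenotypeSchemaError(
                "duplicate record for (individual, trait, time) = "
                f"({first['individual']}, {first['trait']}, {first['time']})"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def trait(self, name: str, time: float | None = None) -> pd.DataFrame:
        sub = self.df[self.df["trait"] == name]
        if time is not None:
            sub = sub[sub["time"] == time]
        return sub.reset_index(drop=True)

    def final_time(self, name: str) -> pd.DataFrame:
        """Records of a trait at its last survey time per individual."""
        sub = self.df[self.df["trait"] == name]
        idx = sub.groupby("individual")["time"].idxmax()
        return sub.loc[idx].reset_index(drop=True)


def read_phenotypes(path: str | Path, sep: str | None = None) -> PhenotypeTable:
    """Read a delimited phenotype table (CSV/TSV autodetected from extension)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)
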