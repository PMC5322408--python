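"""Typed data containers, file readers/writers and run configuration.

The package works on two tables that travel together through every stage:

* :class:`GenotypeTable` — diploid multilocus microsatellite genotypes,
  exchanged on disk in the Genepop dialect (2- or 3-digit allele codes,
  ``Pop`` separators, zero codes for missing calls).
* a *phenotype table* — a plain :class:`pandas.DataFrame` with one row per
  fish (standard length, gill-raker count, age, capture depth/date/mesh,
  site coordinates, net type) read from delimited text.

Allele codes are kept verbatim (raw fragment sizes are legal codes); no
binning is applied.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("depthcline")

__all__ = [
    "GenotypeTable",
    "RunConfig",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_phenotypes",
    "write_phenotypes",
    "load_config",
    "dms_to_decimal",
]


class GenepopParseError(ValueError):
    """Raised on malformed Genepop input; message carries file and line."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with a missing-data mask.

    ``calls`` has shape ``(n, n_loci, 2)`` with positive integer allele
    codes; 0 denotes a missing gene. A locus call is either fully typed
    (both codes > 0) or fully missing (both 0).
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray
    pop: np.ndarray | None = None  # optional per-individual population label

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n, n_loci, 2)")
        if self.calls.shape[0] != len(self.individual_ids):
            raise ValueError("number of ids does not match calls")
        if self.calls.shape[1] != len(self.locus_names):
            raise ValueError("number of locus names does not match calls")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be non-negative")
        half = (self.calls == 0).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing calls are not allowed")
        if self.pop is not None:
            self.pop = np.asarray(self.pop)
            if self.pop.shape[0] != self.calls.shape[0]:
                raise ValueError("pop labels do not match number of rows")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean (n, n_loci) mask, True where the call is missing."""
        return self.calls[:, :, 0] == 0

    def subset(self, index: np.ndarray) -> "GenotypeTable":
        """Row subset by boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeTable(
            [self.individual_ids[i] for i in index],
            list(self.locus_names),
            self.calls[index],
            None if self.pop is None else self.pop[index],
        )


# ---------------------------------------------------------------------------
# Genepop dialect
# ---------------------------------------------------------------------------


def _decode_call(token: str, width: int, path: str, lineno: int) -> tuple[int, int]:
    if len(token) != 2 * width or not token.isdigit():
        raise GenepopParseError(
            f"{path}:{lineno}: bad genotype token {token!r} for {width}-digit coding"
        )
    a, b = int(token[:width]), int(token[width:])
    if (a == 0) != (b == 0):
        raise GenepopParseError(f"{path}:{lineno}: half-missing call {token!r}")
    return a, b


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a Genepop file (2- or 3-digit coding, auto-detected).

    ``Pop`` separators are preserved as a population label column
    (``pop``, values ``pop1``, ``pop2``, ... unless the first individual id
    of a population names it). Zero-coded calls become missing.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenepopParseError(f"{path}: empty file")
    # header: title line, then locus names until the first "Pop"
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        # header-only file: an empty table
        return GenotypeTable([], locus_names, np.zeros((0, len(locus_names), 2), int))
    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_counter = 0
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_counter += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"{path}:{lineno}: expected 'id , genotypes'")
        ind_id, geno = line.split(",", 1)
        tokens = geno.split()
        if width is None and tokens:
            if len(tokens[0]) == 4:
                width = 2
            elif len(tokens[0]) == 6:
                width = 3
            else:
                raise GenepopParseError(
                    f"{path}:{lineno}: cannot infer 2/3-digit coding from {tokens[0]!r}"
                )
        if len(tokens) != len(locus_names):
            raise GenepopParseError(
                f"{path}:{lineno}: {len(tokens)} genotypes for {len(locus_names)} loci"
            )
        rows.append([_decode_call(t, width, str(path), lineno) for t in tokens])
        ids.append(ind_id.strip())
        pops.append(f"pop{pop_counter}")
    calls = np.array(rows, dtype=np.int64).reshape(len(rows), len(locus_names), 2)
    return GenotypeTable(ids, locus_names, calls, np.array(pops))


def write_genepop(
    table: GenotypeTable, path: str | Path, title: str = "depthcline export", width: int = 3
) -> None:
    """Write ``table`` in Genepop dialect; missing calls are zero-encoded."""
    if table.calls.size and table.calls.max() > 10**width - 1:
        raise ValueError(f"allele codes exceed {width}-digit Genepop coding")
    path = Path(path)
    out = [title]
    out.extend(table.locus_names)
    if table.n_individuals:
        pops = table.pop if table.pop is not None else np.array(["pop1"] * table.n_individuals)
        last = None
        for i in range(table.n_individuals):
            if pops[i] != last:
                out.append("Pop")
                last = pops[i]
            genos = " ".join(
                f"{a:0{width}d}{b:0{width}d}" for a, b in table.calls[i]
            )
            out.append(f"{table.individual_ids[i]} , {genos}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(\d+(?:\.\d+)?)\s*[°d]\s*(?:(\d+(?:\.\d+)?)\s*[′'m]\s*)?(?:(\d+(?:\.\d+)?)\s*[″"s]\s*)?([NSEW]?)\s*$"""
)


def dms_to_decimal(value: str | float) -> float:
    """Convert a degrees-minutes-seconds string (e.g. 47°01′36.37″) to decimal degrees."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _DMS_RE.match(str(value))
    if not m:
        return float(value)  # already decimal text
    deg = float(m.group(1)) + float(m.group(2) or 0) / 60 + float(m.group(3) or 0) / 3600
    if m.group(4) in ("S", "W"):
        deg = -deg
    return deg


PHENO_NUMERIC = {"sl": float, "gr": "Int64", "age": "Int64", "depth": float, "mesh": float}


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a delimited phenotype/capture table (separator sniffed).

    Expected columns (case-insensitive; extras pass through): ``id``, ``sl``
    (standard length, mm), ``gr`` (gill-raker count), ``age`` (years),
    ``depth`` (m), ``date`` (ISO-8601), ``mesh`` (mm), ``site_lat`` /
    ``site_lon`` (decimal degrees or DMS strings), ``net_type``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    errors: list[str] = []
    for col, typ in PHENO_NUMERIC.items():
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            for idx in df.index[bad]:
                errors.append(f"row {idx + 2}: non-numeric {col}={df.loc[idx, col]!r}")
            df[col] = coerced.astype(typ)
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
        # days since first survey date, for regression use
        df["date_days"] = (df["date"] - df["date"].min()).dt.days
    for col in ("site_lat", "site_lon"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map(dms_to_decimal)
    if "sl" in df.columns and (df["sl"].dropna() <= 0).any():
        raise ValueError(f"{path}: standard length must be positive where present")
    if "gr" in df.columns and (df["gr"].dropna() < 1).any():
        raise ValueError(f"{path}: gill-raker counts must be >= 1 where present")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated run configuration with field-scale defaults.

    Permutation defaults mirror common practice for microsatellite surveys
    (10,000 for F-statistics, 1,000 for Mantel tests); ``full=False``
    switches the heavy Markov-chain HWE test to desk-scale defaults.
    """

    genotypes: str | None = None
    phenotypes: str | None = None
    preset: str | None = None
    grouping: str = "sl_class"
    fst_permutations: int = 10_000
    mantel_permutations: int = 1_000
    hwe_chain: int = 100_000
    hwe_dememorization: int = 1_000
    rarefaction_g: int | None = None
    fdr_q: float = 0.05
    seed: int = 0
    outdir: str = "depthcline_out"
    full: bool = False

    def __post_init__(self) -> None:
        if self.fst_permutations < 99 or self.mantel_permutations < 99:
            raise ValueError("permutation counts must be >= 99")
        if self.rarefaction_g is not None and self.rarefaction_g < 2:
            raise ValueError("rarefaction size must be >= 2 genes")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.full:
            # survey-scale permutation/chain settings
            self.fst_permutations = max(self.fst_permutations, 10_000)
            self.hwe_chain = max(self.hwe_chain, 10_000_000)
            self.hwe_dememorization = max(self.hwe_dememorization, 10_000)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML/JSON run configuration; unknown keys warn, bad values fail."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
    cfg = RunConfig(**{k: v for k, v in data.items() if k in known})
    logger.info("run config loaded (seed=%d)", cfg.seed)
    return cfg
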