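"""Tabular input/output with strict validation.

Formats handled here:

* counts — TSV, first column ``gene_id``, remaining columns one per sample,
  integer read counts.  ``#``-prefixed lines at the top are provenance
  comments and are skipped.
* group map — two-column TSV (``sample_id``, ``group``).
* phenotypes — CSV, one row per mouse, complete (no missing cells allowed).
* gene sets — GMT (set name, description, members, tab separated) or a plain
  one-gene-per-line list.

All writers prepend a ``#``-prefixed provenance header (tool version and,
when available, the seed / config hash of the run that produced the table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

#: canonical phenotype table columns (besides sample_id / group / body_weight)
PHENOTYPE_COLUMNS = (
    "quadriceps_w",
    "tibialis_anterior_w",
    "gastrocnemius_w",
    "hindlimb_thickness",
    "total_muscle",
    "total_fat",
    "muscle_fat_ratio",
    "grip_strength",
)

#: phenotypes that are per-animal masses/forces and get per-100 g body-weight
#: normalization; the muscle-to-fat ratio is dimensionless and is left as is.
NORMALIZED_PHENOTYPES = tuple(p for p in PHENOTYPE_COLUMNS if p != "muscle_fat_ratio")


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with per-sample group labels.

    ``counts`` is a pandas DataFrame indexed by gene ID with sample IDs as
    columns; ``groups`` maps every sample ID to its experimental group label.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(self.groups)
        dup_g = self.counts.index[self.counts.index.duplicated()].unique()
        if len(dup_g):
            raise ValidationError(f"duplicate gene ID(s): {', '.join(map(str, dup_g))}")
        dup_s = self.counts.columns[self.counts.columns.duplicated()].unique()
        if len(dup_s):
            raise ValidationError(f"duplicate sample ID(s): {', '.join(map(str, dup_s))}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"sample(s) missing from group map: {', '.join(missing)}")
        self.groups = self.groups.loc[self.counts.columns]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValidationError(
                    "non-integer count at gene "
                    f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts are not allowed")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in(self, *group_labels: str) -> list[str]:
        """Sample IDs belonging to any of the given groups, in column order."""
        wanted = set(group_labels)
        return [s for s in self.sample_ids if self.groups[s] in wanted]

    def __eq__(self, other: object) -> bool:  # pragma: no cover - trivial
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.groups.equals(other.groups)


@dataclass
class GeneSet:
    """A named gene set (e.g. the ChEA Klf4 target list)."""

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        self.members = frozenset(self.members)

    def contains(self, gene_id: str, case_insensitive: bool = False) -> bool:
        if gene_id in self.members:
            return True
        if case_insensitive:
            lowered = {m.lower() for m in self.members}
            return gene_id.lower() in lowered
        return False

    def intersect(self, genes: Iterable[str], case_insensitive: bool = False) -> set[str]:
        """Members of ``genes`` present in this set (case-preserving on input)."""
        if not case_insensitive:
            return set(genes) & set(self.members)
        lowered = {m.lower() for m in self.members}
        return {g for g in genes if g.lower() in lowered}

    def __len__(self) -> int:
        return len(self.members)


def _provenance_lines(seed: int | None = None, config_hash: str | None = None) -> list[str]:
    lines = [f"# sarcomark v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config_hash: {config_hash}")
    return lines


def read_counts(path: str | Path, group_map_path: str | Path) -> CountMatrix:
    """Read a counts TSV plus a sample→group map TSV into a CountMatrix.

    All-zero gene rows are retained (they are filtered downstream by the DE
    step, not at ingest).  Duplicate IDs, non-integer cells and samples
    missing from the group map are hard errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    gm = pd.read_csv(group_map_path, sep="\t", comment="#")
    if gm.shape[1] < 2:
        raise ValidationError(f"group map {group_map_path} needs columns sample_id, group")
    groups = pd.Series(
        gm.iloc[:, 1].astype(str).to_numpy(), index=gm.iloc[:, 0].astype(str)
    )
    dup = groups.index[groups.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate sample ID(s) in group map: {', '.join(dup)}")
    return CountMatrix(counts=df, groups=groups)


def write_counts(
    cm: CountMatrix,
    path: str | Path,
    group_map_path: str | Path | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        out = cm.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t")
    if group_map_path is not None:
        gm = pd.DataFrame({"sample_id": cm.sample_ids, "group": cm.groups.to_numpy()})
        with open(group_map_path, "w") as fh:
            for line in _provenance_lines(seed, config_hash):
                fh.write(line + "\n")
            gm.to_csv(fh, sep="\t", index=False)


def validate_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table: complete, positive masses, exact ratio.

    Missing cells are a hard error — every correlation downstream assumes
    complete vectors.
    """
    required = ["sample_id", "group", "body_weight", *PHENOTYPE_COLUMNS]
    missing_cols = [c for c in required if c not in phenotypes.columns]
    if missing_cols:
        raise ValidationError(f"phenotype table missing column(s): {', '.join(missing_cols)}")
    if phenotypes[required].isna().any().any():
        bad = phenotypes[required].isna().any()
        raise ValidationError(
            f"phenotype table has missing cells in: {', '.join(bad.index[bad])}"
        )
    dup = phenotypes["sample_id"][phenotypes["sample_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate sample ID(s) in phenotypes: {', '.join(dup)}")
    masses = ["body_weight", "quadriceps_w", "tibialis_anterior_w", "gastrocnemius_w",
              "total_muscle", "total_fat"]
    if (phenotypes[masses].to_numpy() <= 0).any():
        raise ValidationError("all masses must be strictly positive")
    ratio = phenotypes["total_muscle"] / phenotypes["total_fat"]
    if not np.allclose(ratio, phenotypes["muscle_fat_ratio"], atol=1e-9, rtol=0):
        raise ValidationError("muscle_fat_ratio must equal total_muscle / total_fat")
    return phenotypes


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["sample_id"] = df["sample_id"].astype(str)
    return validate_phenotypes(df)


def write_phenotypes(
    phenotypes: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        phenotypes.to_csv(fh, index=False)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file or a plain one-gene-per-line list.

    A file is treated as GMT when every non-empty line contains a tab; a
    plain list yields a single set named after the file stem.  A GMT line
    with fewer than three fields is an error reported with its line number.
    """
    path = Path(path)
    lines = [
        (i + 1, ln.rstrip("\n"))
        for i, ln in enumerate(path.read_text().splitlines())
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        logger.warning("gene set file %s is empty", path)
        return []
    if all("\t" in ln for _, ln in lines):
        sets = []
        for lineno, ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), need >= 3 "
                    "(name, description, members...)"
                )
            sets.append(
                GeneSet(name=fields[0], description=fields[1],
                        members=frozenset(f for f in fields[2:] if f))
            )
        return sets
    members = frozenset(ln.strip() for _, ln in lines)
    return [GeneSet(name=path.stem, description=f"plain list from {path.name}",
                    members=members)]


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
    index: bool = False,
) -> None:
    """Write an output TSV with the standard provenance header."""
    with open(path, "w") as fh:
        for line in _provenance_lines(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def group_sizes(groups: pd.Series | Mapping[str, str]) -> dict[str, int]:
    s = pd.Series(groups)
    return s.value_counts().to_dict()
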