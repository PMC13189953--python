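"""Domain types and file-format readers/writers.

Every external file the pipeline touches goes through this module: genotype
dosages (VCF or a dosage-TSV dialect), PED-like pedigrees, phenotype and
covariate tables, chromatin-state segmentations (BED4), promoter-capture
interaction files (10-column ibed), GWAS-catalog-like association tables,
per-population allele-frequency tables and JASPAR-like position weight
matrices.

Coordinate conventions, used consistently everywhere downstream:

* variant positions are 1-based (VCF convention);
* interval files are 0-based half-open (BED convention);
* a 1-based position ``p`` lies in interval ``[start, end)`` iff
  ``start < p <= end``.

Missing dosages are coded as ``numpy.nan``, a sentinel that can never collide
with a valid dosage in ``[0, 2]``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("admixgwas")

__all__ = [
    "ParseError",
    "ValidationError",
    "PedigreeError",
    "GenomicInterval",
    "VariantRecord",
    "ChromatinSegment",
    "InteractionRecord",
    "PWM",
    "CohortGenotypes",
    "Pedigree",
    "KNOWN_CHROMATIN_STATES",
    "position_in_interval",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "write_phenotypes",
    "read_segmentation",
    "write_segmentation",
    "read_ibed",
    "write_ibed",
    "read_catalog",
    "write_catalog",
    "read_frequency_table",
    "write_frequency_table",
    "read_pwms",
    "write_pwms",
    "read_sequence_windows",
    "write_sequence_windows",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a documented invariant."""


class PedigreeError(ValueError):
    """Pedigree structure is inconsistent (cycles, missing parents...)."""


#: The 18 chromatin-state mnemonics of the Roadmap expanded model
#: (5 histone marks + H3K27ac).  EnhA1/EnhA2 are active enhancers
#: (H3K4me1 with H3K27ac), EnhG1/EnhG2 genic enhancers (H3K4me1 with
#: H3K36me3), EnhWk weak enhancers.
KNOWN_CHROMATIN_STATES = frozenset(
    [
        "TssA",
        "TssFlnk",
        "TssFlnkU",
        "TssFlnkD",
        "Tx",
        "TxWk",
        "EnhG1",
        "EnhG2",
        "EnhA1",
        "EnhA2",
        "EnhWk",
        "ZNF/Rpts",
        "Het",
        "TssBiv",
        "EnhBiv",
        "ReprPC",
        "ReprPCWk",
        "Quies",
    ]
)


def position_in_interval(pos: int, start: int, end: int) -> bool:
    """True iff 1-based position ``pos`` falls in 0-based half-open [start, end)."""
    return start < pos <= end


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def contains_position(self, pos: int) -> bool:
        return position_in_interval(pos, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with optional post-imputation quality score."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    imputation_r2: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.id}: pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"variant {self.id}: ref == alt allele")
        if self.imputation_r2 is not None and not (0.0 <= self.imputation_r2 <= 1.0):
            raise ValidationError(f"variant {self.id}: imputation R2 outside [0,1]")


@dataclass(frozen=True)
class ChromatinSegment:
    """One chromatin-state interval; ``known`` flags recognised mnemonics."""

    interval: GenomicInterval
    state: str
    known: bool = True


@dataclass(frozen=True)
class InteractionRecord:
    """A promoter-capture contact: bait anchor, other-end anchor, evidence."""

    bait: GenomicInterval
    bait_genes: tuple[str, ...]
    other_end: GenomicInterval
    other_genes: tuple[str, ...]
    read_count: int
    score: float
    timepoint: str | None = None


@dataclass(frozen=True)
class PWM:
    """Position-specific probability matrix over A, C, G, T."""

    motif_id: str
    matrix: tuple[tuple[float, float, float, float], ...]
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if len(self.matrix) < 4:
            raise ValidationError(f"PWM {self.motif_id}: length < 4")
        for i, col in enumerate(self.matrix):
            if abs(sum(col) - 1.0) > 1e-6:
                raise ValidationError(
                    f"PWM {self.motif_id}: column {i} sums to {sum(col)}, not 1"
                )

    def __len__(self) -> int:
        return len(self.matrix)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)


# --------------------------------------------------------------------------
# cohort containers
# --------------------------------------------------------------------------

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "imputation_r2"]


@dataclass
class CohortGenotypes:
    """Dosage matrix plus aligned variant metadata.

    ``dosages`` is ``(n_samples, n_variants)`` float with values in [0, 2] or
    NaN for missing; column ``j`` corresponds to row ``j`` of ``variants``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant id {dup!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} outside [0,2] "
                f"(sample {self.samples[i]}, variant {self.variants['id'].iloc[j]})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: j for j, v in enumerate(self.variants["id"])}
        try:
            return np.asarray([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown variant id {exc.args[0]!r}") from None

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        variant_ids: Sequence[str] | None = None,
    ) -> "CohortGenotypes":
        rows = np.arange(self.n_samples)
        if sample_ids is not None:
            pos = {s: i for i, s in enumerate(self.samples)}
            rows = np.asarray([pos[s] for s in sample_ids], dtype=int)
        cols = np.arange(self.n_variants)
        if variant_ids is not None:
            cols = self.variant_index(variant_ids)
        return CohortGenotypes(
            samples=[self.samples[i] for i in rows],
            variants=self.variants.iloc[cols].reset_index(drop=True),
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
        )


FOUNDER = "0"  # parent marker used for founders in PED-like files


@dataclass
class Pedigree:
    """Family structure: individuals, parents, sex, founder admixture.

    ``table`` has columns ``individual``, ``father``, ``mother``, ``sex``
    (1 = male, 2 = female); ``FOUNDER`` ("0") marks a missing/founder parent.
    ``founder_admixture`` optionally gives per-founder ancestry proportions
    (rows indexed by individual id, one column per ancestral population).
    """

    table: pd.DataFrame
    founder_admixture: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        ids = self.table["individual"]
        if ids.duplicated().any():
            raise PedigreeError(f"duplicate individual id {ids[ids.duplicated()].iloc[0]!r}")
        known = set(ids)
        for col in ("father", "mother"):
            for parent in self.table[col]:
                if parent != FOUNDER and parent not in known:
                    raise PedigreeError(f"unknown {col} id {parent!r}")
        # both parents present or both absent keeps gene transmission simple
        half = (self.table["father"] == FOUNDER) != (self.table["mother"] == FOUNDER)
        if half.any():
            raise PedigreeError(
                f"individual {ids[half].iloc[0]!r} has exactly one known parent"
            )
        self._order = self._topological_order()

    @property
    def individuals(self) -> list[str]:
        return list(self.table["individual"])

    def is_founder(self, individual: str) -> bool:
        row = self.table.loc[self.table["individual"] == individual].iloc[0]
        return row["father"] == FOUNDER

    @property
    def founders(self) -> list[str]:
        mask = self.table["father"] == FOUNDER
        return list(self.table.loc[mask, "individual"])

    def parents(self) -> dict[str, tuple[str, str]]:
        return {
            r.individual: (r.father, r.mother)
            for r in self.table.itertuples(index=False)
        }

    def topological_order(self) -> list[str]:
        """Individuals ordered so every parent precedes its offspring."""
        return list(self._order)

    def _topological_order(self) -> list[str]:
        parents = self.parents()
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self.table["individual"]:
            if state.get(start) == 1:
                continue
            stack = [(start, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(f"pedigree cycle involving {node!r}")
                state[node] = 0
                stack.append((node, True))
                for p in parents[node]:
                    if p != FOUNDER and state.get(p) != 1:
                        if state.get(p) == 0:
                            raise PedigreeError(f"pedigree cycle involving {p!r}")
                        stack.append((p, False))
        return order


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "vcf") -> CohortGenotypes:
    """Read a genotype file into a :class:`CohortGenotypes`.

    ``format="vcf"`` reads a biallelic VCF via cyvcf2, preferring per-sample
    DS (dosage) over GT; ``format="dosage-tsv"`` reads the package's
    variants-by-samples TSV dialect (metadata columns then one column per
    sample, empty cells = missing).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> CohortGenotypes:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF contains no samples")
    meta_rows = []
    dosage_cols = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ParseError(
                f"{path}: variant {variant.ID or variant.POS} is not biallelic"
            )
        r2 = variant.INFO.get("R2")
        try:
            ds = variant.format("DS")
        except KeyError:  # DS not declared in the header
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(col < 0, np.nan, col)  # cyvcf2 codes missing as <0
        else:
            col = np.empty(len(samples))
            for i, gt in enumerate(variant.genotypes):
                alleles = gt[:-1]
                col[i] = np.nan if min(alleles) < 0 else float(sum(a > 0 for a in alleles))
        meta_rows.append(
            (
                variant.CHROM,
                variant.POS,
                variant.ID or f"{variant.CHROM}:{variant.POS}",
                variant.REF,
                variant.ALT[0],
                float(r2) if r2 is not None else np.nan,
            )
        )
        dosage_cols.append(col)
    if not meta_rows:
        raise ParseError(f"{path}: VCF contains no variants")
    variants = pd.DataFrame(meta_rows, columns=VARIANT_COLUMNS)
    return CohortGenotypes(samples, variants, np.column_stack(dosage_cols))


def _read_dosage_tsv(path: Path) -> CohortGenotypes:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "id": str}, float_precision="round_trip"
    )
    missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing metadata columns {missing_cols} in header")
    if len(df) == 0:
        raise ParseError(f"{path}: no variants")
    samples = [c for c in df.columns if c not in VARIANT_COLUMNS]
    if not samples:
        raise ParseError(f"{path}: no sample columns in header")
    dosages = df[samples].to_numpy(dtype=float).T  # rows were variants
    return CohortGenotypes(samples, df[VARIANT_COLUMNS].copy(), dosages)


def write_dosage_tsv(genotypes: CohortGenotypes, path: str | Path) -> None:
    """Write the dosage-TSV dialect (variants as rows; empty cell = missing)."""
    df = genotypes.variants.copy()
    sample_cols = pd.DataFrame(
        genotypes.dosages.T, columns=genotypes.samples, index=df.index
    )
    df = pd.concat([df, sample_cols], axis=1)
    # %.17g is lossless for float64, keeping write->read an exact round trip
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


def write_vcf(genotypes: CohortGenotypes, path: str | Path) -> None:
    """Write a minimal biallelic VCF with DS (and GT for integral dosages)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j, v in enumerate(genotypes.variants.itertuples(index=False)):
            info = "." if pd.isna(v.imputation_r2) else f"R2={v.imputation_r2:.6g}"
            cells = []
            for i in range(genotypes.n_samples):
                d = genotypes.dosages[i, j]
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    if float(d).is_integer():
                        gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
                    else:
                        gt = "./."
                    cells.append(f"{gt}:{d:.6g}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


# --------------------------------------------------------------------------
# pedigree / phenotype tables
# --------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED-like TSV: individual, father, mother, sex [, adx_* columns]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["individual", "father", "mother", "sex"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing pedigree columns {missing}")
    df["sex"] = df["sex"].astype(int)
    adx_cols = [c for c in df.columns if c.startswith("adx_")]
    admix = None
    if adx_cols:
        admix = df.loc[df["father"] == FOUNDER, ["individual"] + adx_cols].copy()
        admix = admix.set_index("individual").astype(float)
        admix.columns = [c[len("adx_"):] for c in adx_cols]
    return Pedigree(df[required].copy(), admix)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    df = pedigree.table.copy()
    if pedigree.founder_admixture is not None:
        adm = pedigree.founder_admixture.add_prefix("adx_")
        df = df.merge(adm, left_on="individual", right_index=True, how="left")
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: phenotype table needs a sample_id column")
    return df


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# chromatin-state segmentation (BED4)
# --------------------------------------------------------------------------


def read_segmentation(path: str | Path) -> list[ChromatinSegment]:
    """Read a BED4 chromatin-state file; validates sortedness and no overlap."""
    segments: list[ChromatinSegment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: expected 4 BED columns, got {len(parts)}")
            chrom, start_s, end_s, state = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from None
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start >= end ({start} >= {end})")
            known = state in KNOWN_CHROMATIN_STATES
            if not known:
                logger.warning("%s:%d: unknown chromatin state %r", path, ln, state)
            segments.append(
                ChromatinSegment(GenomicInterval(chrom, start, end), state, known)
            )
    return sort_and_validate_segments(segments)


def sort_and_validate_segments(
    segments: Sequence[ChromatinSegment],
) -> list[ChromatinSegment]:
    """Sort segments per chromosome and reject overlapping ones (abutting OK)."""
    out = sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start))
    for a, b in zip(out, out[1:]):
        if a.interval.chrom == b.interval.chrom and b.interval.start < a.interval.end:
            raise ValidationError(
                f"overlapping segments on {a.interval.chrom}: "
                f"[{a.interval.start},{a.interval.end}) and "
                f"[{b.interval.start},{b.interval.end})"
            )
    return out


def write_segmentation(segments: Sequence[ChromatinSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t{s.state}\n")


# --------------------------------------------------------------------------
# promoter-capture interactions (ibed)
# --------------------------------------------------------------------------

IBED_HEADER = (
    "bait_chr\tbait_start\tbait_end\tbait_name\t"
    "otherEnd_chr\totherEnd_start\totherEnd_end\totherEnd_name\tN_reads\tscore"
)


def _parse_gene_names(name: str, delimiter: str) -> tuple[str, ...]:
    if name in (".", ""):
        return ()
    return tuple(g for g in name.split(delimiter) if g and g != ".")


def read_ibed(
    path: str | Path,
    timepoint: str | None = None,
    gene_delimiter: str = ";",
) -> list[InteractionRecord]:
    """Read a 10-column ibed file; ``timepoint`` labels every record.

    Anchor names are parsed into gene symbols split on ``gene_delimiter``;
    a "." name yields an empty gene tuple.
    """
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0] in ("bait_chr", "bait_chrom"):
                continue  # optional header
            if len(parts) != 10:
                raise ParseError(f"{path}:{ln}: expected 10 ibed columns, got {len(parts)}")
            try:
                bait = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                other = GenomicInterval(parts[4], int(parts[5]), int(parts[6]))
                n_reads = int(parts[8])
                score = float(parts[9])
            except ValueError:
                raise ParseError(f"{path}:{ln}: malformed numeric field") from None
            records.append(
                InteractionRecord(
                    bait=bait,
                    bait_genes=_parse_gene_names(parts[3], gene_delimiter),
                    other_end=other,
                    other_genes=_parse_gene_names(parts[7], gene_delimiter),
                    read_count=n_reads,
                    score=score,
                    timepoint=timepoint,
                )
            )
    if not records:
        logger.warning("%s: empty ibed file", path)
    return records


def write_ibed(
    records: Sequence[InteractionRecord],
    path: str | Path,
    gene_delimiter: str = ";",
) -> None:
    def name(genes: tuple[str, ...]) -> str:
        return gene_delimiter.join(genes) if genes else "."

    with open(path, "w") as fh:
        fh.write(IBED_HEADER + "\n")
        for r in records:
            fh.write(
                f"{r.bait.chrom}\t{r.bait.start}\t{r.bait.end}\t{name(r.bait_genes)}\t"
                f"{r.other_end.chrom}\t{r.other_end.start}\t{r.other_end.end}\t"
                f"{name(r.other_genes)}\t{r.read_count}\t{r.score:.6g}\n"
            )


# --------------------------------------------------------------------------
# catalog and allele-frequency tables
# --------------------------------------------------------------------------

CATALOG_COLUMNS = ["variant_id", "chrom", "pos", "trait", "p"]


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-catalog-like table: variant_id, chrom, pos, trait, p."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str, "trait": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing catalog columns {missing}")
    return df[CATALOG_COLUMNS].copy()


def write_catalog(table: pd.DataFrame, path: str | Path) -> None:
    table[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    """Read per-population allele frequencies, one row per variant id."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    if "variant_id" not in df.columns:
        raise ParseError(f"{path}: frequency table needs a variant_id column")
    df = df.set_index("variant_id")
    values = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((values < 0) | (values > 1)):
            raise ValidationError(f"{path}: allele frequency outside [0,1]")
    return df


def write_frequency_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="variant_id", na_rep="")


# --------------------------------------------------------------------------
# position weight matrices (JASPAR-like text)
# --------------------------------------------------------------------------

_PWM_ROW = re.compile(r"^([ACGT])\s*\[?\s*([-0-9.eE+\s]+?)\s*\]?\s*$")


def read_pwms(path: str | Path, pseudocount: float = 0.5) -> list[PWM]:
    """Read JASPAR-like PWM text (``>id`` then A/C/G/T count or frequency rows).

    Count matrices are converted to probabilities with ``pseudocount`` added
    per cell; rows already summing to ~1 per column are taken as-is.
    """
    pwms: list[PWM] = []
    current_id: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal current_id, rows
        if current_id is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise ParseError(f"PWM {current_id}: needs exactly A, C, G, T rows")
        mat = np.asarray([rows[b] for b in "ACGT"], dtype=float).T  # (L, 4)
        if mat.shape[0] < 4:
            raise ValidationError(f"PWM {current_id}: length < 4")
        colsums = mat.sum(axis=1)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            mat = mat + pseudocount
            mat = mat / mat.sum(axis=1, keepdims=True)
        pwms.append(PWM(current_id, tuple(map(tuple, mat))))
        current_id, rows = None, {}

    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0]
                continue
            m = _PWM_ROW.match(line)
            if m is None or current_id is None:
                raise ParseError(f"{path}:{ln}: unrecognized PWM line {line!r}")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    flush()
    if not pwms:
        raise ParseError(f"{path}: no PWMs found")
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\n")
            mat = p.as_array()
            for bi, base in enumerate("ACGT"):
                cells = " ".join(f"{x:.8g}" for x in mat[:, bi])
                fh.write(f"{base} [ {cells} ]\n")


# --------------------------------------------------------------------------
# sequence windows (FASTA)
# --------------------------------------------------------------------------


def read_sequence_windows(path: str | Path) -> dict[str, str]:
    """Read a FASTA of per-variant sequence windows keyed by record id."""
    from Bio import SeqIO

    windows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not windows:
        raise ParseError(f"{path}: no FASTA records")
    return windows


def write_sequence_windows(windows: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in windows.items():
            fh.write(f">{name}\n{seq}\n")
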