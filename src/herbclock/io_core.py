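"""Shared data model and readers/writers for the standard formats.

Internal coordinate convention is 1-based closed (VCF/GFF native); BED input
is converted on read.  Genotype calls are haploid lineage states: 0 =
ancestral/reference allele, 1 = derived allele, -1 = missing.  Heterozygous
calls are rejected by default because the lineage is selfing and calls are
expected homozygous; ``het_policy="missing"`` downgrades them instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1

#: annotation classes in precedence order (highest wins on overlap);
#: unannotated positions fall through to "intergenic".
PRECEDENCE = ("coding", "utr5", "utr3", "intronic", "transposon", "pseudogene", "other")

ANNOTATION_CLASSES = PRECEDENCE + ("intergenic",)

ERAS = ("herbarium", "modern")

# GFF3/BED feature-type -> internal class. Unknown types map to "other".
FEATURE_CLASS = {
    "cds": "coding",
    "coding": "coding",
    "five_prime_utr": "utr5",
    "utr5": "utr5",
    "three_prime_utr": "utr3",
    "utr3": "utr3",
    "intron": "intronic",
    "intronic": "intronic",
    "transposable_element": "transposon",
    "transposable_element_gene": "transposon",
    "transposon_fragment": "transposon",
    "transposon": "transposon",
    "pseudogene": "pseudogene",
    "pseudogenic_transcript": "pseudogene",
    "intergenic": "intergenic",
    "other": "other",
}

# feature types consumed for intron derivation, never classes of their own
_STRUCTURAL = {"gene", "mrna", "exon", "chromosome", "region", "protein"}


class HerbclockError(ValueError):
    """Fatal input or precondition violation."""


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """One dated, geolocated sample record."""

    sample_id: str
    year: int
    latitude: float
    longitude: float
    era: str  # "herbarium" | "modern"

    def __post_init__(self):
        if not (1500 <= self.year <= 2100):
            raise HerbclockError(f"{self.sample_id}: year {self.year} outside [1500, 2100]")
        if self.era not in ERAS:
            raise HerbclockError(f"{self.sample_id}: unknown era {self.era!r}")


def validate_meta(meta: list[SampleMeta]) -> None:
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise HerbclockError(f"duplicate sample ids: {dup}")
    modern_years = [m.year for m in meta if m.era == "modern"]
    if modern_years:
        ymax = max(modern_years)
        for m in meta:
            if m.era == "herbarium" and m.year > ymax:
                raise HerbclockError(
                    f"herbarium sample {m.sample_id} ({m.year}) postdates newest modern sample ({ymax})"
                )


def read_sample_meta(path) -> list[SampleMeta]:
    """Read a sample metadata TSV (sample_id, year, latitude, longitude, era)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "year", "latitude", "longitude", "era"}
    missing = required - set(df.columns)
    if missing:
        raise HerbclockError(f"metadata file missing columns: {sorted(missing)}")
    meta = [
        SampleMeta(r.sample_id, int(r.year), float(r.latitude), float(r.longitude), str(r.era))
        for r in df.itertuples()
    ]
    validate_meta(meta)
    return meta


def write_sample_meta(meta: list[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "year": [m.year for m in meta],
            "latitude": [m.latitude for m in meta],
            "longitude": [m.longitude for m in meta],
            "era": [m.era for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Sites x samples matrix of derived-allele calls against a pseudo-reference.

    ``sites`` columns: chrom, pos, anc, der, annotation_class.
    ``calls``: int8 matrix, 0 ancestral / 1 derived / -1 missing.
    ``accessible_length``: per-class callable bp plus ``"total"``.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    samples: list[str]
    accessible_length: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise HerbclockError(
                f"calls shape {self.calls.shape} != (n_sites={len(self.sites)}, n_samples={len(self.samples)})"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def derived_counts_per_sample(self) -> np.ndarray:
        return (self.calls == 1).sum(axis=0)

    def callable_per_sample(self) -> np.ndarray:
        return (self.calls != MISSING).sum(axis=0)

    def derived_freqs(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (derived count, non-missing count)."""
        der = (self.calls == 1).sum(axis=1)
        nm = (self.calls != MISSING).sum(axis=1)
        return der, nm

    def subset_sites(self, mask) -> "VariantTable":
        mask = np.asarray(mask)
        return VariantTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.calls[mask],
            list(self.samples),
            dict(self.accessible_length),
        )

    def subset_samples(self, keep: list[str]) -> "VariantTable":
        idx = [self.samples.index(s) for s in keep]
        return VariantTable(
            self.sites.copy(), self.calls[:, idx], list(keep), dict(self.accessible_length)
        )

    def sorted(self) -> "VariantTable":
        order = np.lexsort((self.sites["pos"].to_numpy(), self.sites["chrom"].to_numpy()))
        return VariantTable(
            self.sites.iloc[order].reset_index(drop=True),
            self.calls[order],
            list(self.samples),
            dict(self.accessible_length),
        )


def read_vcf(path, meta: list[SampleMeta] | None = None, het_policy: str = "fatal",
             accessible_length: dict | None = None) -> VariantTable:
    """Read a VCF of haploid / homozygous-diploid biallelic SNP calls.

    Parameters
    ----------
    meta
        If given, every VCF sample must have a metadata record.
    het_policy
        "fatal" (default) raises on heterozygous diploid calls; "missing"
        converts them to missing.
    """
    if het_policy not in ("fatal", "missing"):
        raise HerbclockError(f"unknown het_policy {het_policy!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if meta is not None:
        known = {m.sample_id for m in meta}
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise HerbclockError(f"VCF samples absent from metadata: {unknown}")

    chroms, poss, ancs, ders, classes, rows = [], [], [], [], [], []
    n_dropped = 0
    for rec in vcf:
        if not rec.ALT:
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for k, g in enumerate(rec.genotypes):
            alleles = g[:-1]  # last element is the phased flag
            alleles = [a for a in alleles if a is not None]
            if all(a == -1 for a in alleles):
                row[k] = MISSING
            elif len(set(a for a in alleles if a != -1)) > 1:
                if het_policy == "fatal":
                    raise HerbclockError(
                        f"heterozygous call at {rec.CHROM}:{rec.POS} sample {samples[k]}"
                    )
                row[k] = MISSING
            else:
                row[k] = 1 if max(alleles) >= 1 else 0
        if (row == MISSING).all():
            n_dropped += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        ancs.append(rec.REF)
        ders.append(rec.ALT[0])
        classes.append((rec.INFO.get("ANN") or "intergenic"))
        rows.append(row)
    if n_dropped:
        log.info("dropped %d all-missing sites", n_dropped)

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "anc": ancs, "der": ders, "annotation_class": classes}
    )
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    vt = VariantTable(sites, calls, samples, dict(accessible_length or {}))
    return vt.sorted()


def write_vcf(v: VariantTable, path) -> None:
    """Write a minimal haploid VCF 4.2 with the ANN info tag carrying the class."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(v.samples) + "\n")
        code = {0: "0", 1: "1", MISSING: "."}
        for i, s in enumerate(v.sites.itertuples()):
            gts = "\t".join(code[int(c)] for c in v.calls[i])
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.anc}\t{s.der}\t.\tPASS\tANN={s.annotation_class}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# annotation intervals
# ---------------------------------------------------------------------------

def _merge(iv: np.ndarray) -> np.ndarray:
    """Union of 1-based closed intervals, returned sorted and disjoint."""
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def _subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a \\ b for merged interval arrays (1-based closed)."""
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be < cur or bs > e:
                continue
            if bs > cur:
                out.append([cur, bs - 1])
            cur = max(cur, be + 1)
            if cur > e:
                break
        if cur <= e:
            out.append([cur, e])
    return np.array(out, dtype=np.int64) if out else np.empty((0, 2), dtype=np.int64)


def _length(iv: np.ndarray) -> int:
    return int((iv[:, 1] - iv[:, 0] + 1).sum()) if len(iv) else 0


@dataclass
class AnnotationMap:
    """Per-chromosome, per-class interval sets, disjoint after precedence.

    ``intervals[chrom][cls]`` is an (n, 2) array of 1-based closed intervals.
    """

    intervals: dict[str, dict[str, np.ndarray]]
    class_lengths: dict[str, int]

    def classify(self, chrom: str, pos: int) -> str:
        by_class = self.intervals.get(chrom)
        if by_class is None:
            return "intergenic"
        for cls in PRECEDENCE:
            iv = by_class.get(cls)
            if iv is None or len(iv) == 0:
                continue
            j = np.searchsorted(iv[:, 0], pos, side="right") - 1
            if j >= 0 and pos <= iv[j, 1]:
                return cls
        return "intergenic"


def read_annotations(path, dialect: str) -> AnnotationMap:
    """Read a GFF3 or BED annotation file into an :class:`AnnotationMap`.

    GFF3 coordinates are used as-is (1-based closed); BED is converted from
    0-based half-open.  Introns are derived as gene spans minus exon unions.
    Overlaps between classes are resolved by :data:`PRECEDENCE`.
    """
    if dialect not in ("gff3", "bed"):
        raise HerbclockError(f"unknown annotation dialect {dialect!r}")
    raw: dict[str, dict[str, list]] = {}
    genes: dict[str, list] = {}
    exons: dict[str, list] = {}

    def add(store, chrom, s, e):
        store.setdefault(chrom, []).append((s, e))

    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()

    unknown_types: set[str] = set()
    for row in df.itertuples(index=False):
        row = tuple(row)
        if dialect == "gff3":
            if len(row) < 5:
                raise HerbclockError(f"malformed GFF3 line: {row}")
            chrom, ftype = str(row[0]), str(row[2]).lower()
            start, end = int(row[3]), int(row[4])
        else:
            if len(row) < 3:
                raise HerbclockError(f"malformed BED line: {row}")
            chrom = str(row[0])
            start, end = int(row[1]) + 1, int(row[2])  # to 1-based closed
            ftype = str(row[3]).lower() if len(row) > 3 and not pd.isna(row[3]) else "other"
        if end < start:
            raise HerbclockError(f"interval end < start at {chrom}:{start}-{end}")
        if ftype in _STRUCTURAL:
            if ftype == "gene":
                add(genes, chrom, start, end)
            elif ftype == "exon":
                add(exons, chrom, start, end)
            continue
        cls = FEATURE_CLASS.get(ftype)
        if cls is None:
            unknown_types.add(ftype)
            cls = "other"
        raw.setdefault(chrom, {}).setdefault(cls, []).append((start, end))
    if unknown_types:
        warnings.warn(f"unknown feature types classified as 'other': {sorted(unknown_types)}")

    # introns := gene span minus exons (only where both are annotated)
    for chrom, giv in genes.items():
        if chrom not in exons:
            continue
        gene_u = _merge(np.array(giv, dtype=np.int64))
        exon_u = _merge(np.array(exons[chrom], dtype=np.int64))
        intr = _subtract(gene_u, exon_u)
        if len(intr):
            raw.setdefault(chrom, {}).setdefault("intronic", []).extend(map(tuple, intr))

    intervals: dict[str, dict[str, np.ndarray]] = {}
    lengths = {cls: 0 for cls in PRECEDENCE}
    for chrom, by_class in raw.items():
        resolved: dict[str, np.ndarray] = {}
        higher = np.empty((0, 2), dtype=np.int64)
        for cls in PRECEDENCE:
            iv = _merge(np.array(by_class.get(cls, []), dtype=np.int64).reshape(-1, 2))
            iv = _subtract(iv, higher)
            if len(iv):
                resolved[cls] = iv
                higher = _merge(np.vstack([higher, iv]))
                lengths[cls] += _length(iv)
        intervals[chrom] = resolved
    return AnnotationMap(intervals, lengths)


def classify_sites(v: VariantTable, a: AnnotationMap) -> VariantTable:
    """Assign exactly one annotation class to every site via precedence."""
    classes = []
    missing_chroms = set()
    for s in v.sites.itertuples():
        if s.chrom not in a.intervals:
            missing_chroms.add(s.chrom)
        classes.append(a.classify(s.chrom, int(s.pos)))
    if missing_chroms:
        warnings.warn(f"chromosomes absent from annotation map: {sorted(missing_chroms)}")
    sites = v.sites.copy()
    sites["annotation_class"] = classes
    counts = pd.Series(classes).value_counts().to_dict()
    log.info("classified %d sites: %s", len(classes), counts)
    acc = dict(v.accessible_length)
    for cls, n in a.class_lengths.items():
        acc.setdefault(cls, n)
    return VariantTable(sites, v.calls.copy(), list(v.samples), acc)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Long-format phenotype records (sample_id, trait, replicate, value)."""

    data: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "trait", "replicate", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise HerbclockError(f"phenotype table missing columns: {sorted(missing)}")

    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def accession_means(self, trait: str) -> pd.Series:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise HerbclockError(f"no phenotype records for trait {trait!r}")
        return sub.groupby("sample_id")["value"].mean()


def read_phenotypes(path, meta: list[SampleMeta] | None = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "trait": str})
    tbl = PhenotypeTable(df)
    if meta is not None:
        known = {m.sample_id for m in meta}
        unknown = sorted(set(df["sample_id"]) - known)
        if unknown:
            raise HerbclockError(f"phenotype sample ids absent from metadata: {unknown}")
    return tbl


def write_phenotypes(p: PhenotypeTable, path) -> None:
    p.data.to_csv(path, sep="\t", index=False)
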