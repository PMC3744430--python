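"""Readers and writers: VCF regions, phenotype tables, results.

Coordinates: BED input is 0-based half-open, ``chr:start-end`` strings are
1-based inclusive; internally everything is 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .effects import GenotypeRegion, PhenotypeTable, orient_and_maf
from .simulate import TraitModel

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSpec",
    "ResultsRow",
    "read_regions",
    "read_vcf_region",
    "read_phenotypes",
    "write_results",
    "write_vcf",
    "write_phenotypes",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named genomic interval, stored 0-based half-open."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.name}: start must be < end")

    @classmethod
    def from_string(cls, text: str, name: str | None = None) -> "RegionSpec":
        """Parse ``chr:start-end`` (1-based inclusive)."""
        m = re.fullmatch(r"([\w.]+):([\d,]+)-([\d,]+)", text.strip())
        if not m:
            raise ValueError(f"cannot parse region {text!r} (expect chr:start-end)")
        chrom = m.group(1)
        start1 = int(m.group(2).replace(",", ""))
        end1 = int(m.group(3).replace(",", ""))
        return cls(name=name or text.strip(), chromosome=chrom, start=start1 - 1, end=end1)


@dataclass
class ResultsRow:
    """One region-test result with its reproducibility metadata."""

    region: str
    test: str
    n_variants: int
    n_excluded: int
    S: float
    c: float
    z: float
    p_asymptotic: float
    p_permutation: float | None
    n_permutations: int
    maf_min: float
    maf_max: float
    seed: int | None


def read_regions(path: str | Path) -> list[RegionSpec]:
    """Read regions from a BED file (0-based half-open) or a chr:start-end list."""
    specs: list[RegionSpec] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) >= 3 and fields[1].isdigit() and fields[2].isdigit():
                name = fields[3] if len(fields) > 3 else f"{fields[0]}:{fields[1]}-{fields[2]}"
                specs.append(
                    RegionSpec(name=name, chromosome=fields[0],
                               start=int(fields[1]), end=int(fields[2]))
                )
            else:
                specs.append(RegionSpec.from_string(fields[0]))
    if not specs:
        raise ValueError(f"no regions parsed from {path}")
    return specs


def read_vcf_region(
    path: str | Path, region: RegionSpec | None = None, dosage_mode: str = "auto"
) -> GenotypeRegion:
    """Load a dosage matrix for one region from a VCF.

    ``dosage_mode``: ``auto`` uses the DS FORMAT field when present, else GT
    converted to {0,1,2}; ``gt``/``ds`` force one source.  Multiallelic
    records are skipped with a counted warning (their minor-allele semantics
    are ambiguous for rare-variant MAF windows).  Missing genotypes are NaN.
    Uses an index for the region query when available, else a full scan.
    """
    if dosage_mode not in ("auto", "gt", "ds"):
        raise ValueError(f"unknown dosage_mode {dosage_mode!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, positions, columns = [], [], []
    n_multi = 0

    def records():
        if region is None:
            yield from vcf
            return
        query = f"{region.chromosome}:{region.start + 1}-{region.end}"
        try:
            yield from vcf(query)
        except Exception:  # no index: full scan fallback
            for v in VCF(str(path)):
                if v.CHROM == region.chromosome and region.start < v.POS <= region.end:
                    yield v

    for v in records():
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        use_ds = dosage_mode == "ds" or (
            dosage_mode == "auto" and "DS" in (v.FORMAT or [])
        )
        if use_ds:
            ds = np.asarray(v.format("DS"), dtype=float).reshape(len(samples))
        else:
            gt = np.asarray(v.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
            ds = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        positions.append(v.POS)
        columns.append(ds)
    if n_multi:
        logger.warning("skipped %d multiallelic record(s)", n_multi)
    if not columns:
        raise ValueError(f"no biallelic records in region {region.name if region else path}")
    dose = np.column_stack(columns)
    return orient_and_maf(
        GenotypeRegion(
            samples=samples,
            variant_ids=ids,
            positions=np.asarray(positions),
            dosage=dose,
        )
    )


def read_phenotypes(
    path: str | Path,
    trait_name: str,
    covariate_names: list[str] | None = None,
    genotype_samples: list[str] | None = None,
    trait_type: str = "quantitative",
    fid_iid: bool = False,
) -> PhenotypeTable:
    """Read a whitespace/tab-delimited phenotype table with header.

    The first column holds sample ids (or FID/IID pair with ``fid_iid``;
    the IID column is used).  When ``genotype_samples`` is given the table is
    inner-joined to it and the join cardinality logged.
    """
    df = pd.read_csv(path, sep=r"\s+")
    id_col = df.columns[1] if fid_iid else df.columns[0]
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    df = df.set_index(ids)
    if trait_name not in df.columns:
        raise ValueError(f"trait column {trait_name!r} not found")
    if genotype_samples is not None:
        common = [s for s in genotype_samples if s in df.index]
        dropped = len(df) - len(common)
        if dropped:
            logger.info("phenotype join: %d of %d samples analysed (%d dropped)",
                        len(common), len(df), dropped)
        df = df.loc[common]
    trait = pd.to_numeric(df[trait_name], errors="coerce")
    if trait.isna().any():
        raise ValueError(f"non-numeric or missing values in trait column {trait_name!r}")
    cov = None
    if covariate_names:
        missing = [c for c in covariate_names if c not in df.columns]
        if missing:
            raise ValueError(f"covariate column(s) not found: {missing}")
        cov = df[list(covariate_names)].apply(pd.to_numeric, errors="coerce")
        if cov.isna().any().any():
            raise ValueError("non-numeric or missing covariate values")
        cov = cov.to_numpy()
    return PhenotypeTable(
        samples=list(df.index),
        trait=trait.to_numpy(),
        trait_type=trait_type,
        covariates=cov,
        covariate_names=list(covariate_names) if covariate_names else None,
    )


_RESULT_COLUMNS = [
    "region", "test", "n_variants", "n_excluded", "S", "c", "z",
    "p_asymptotic", "p_permutation", "n_permutations", "maf_min", "maf_max", "seed",
]


def write_results(rows: list[ResultsRow], path: str | Path) -> None:
    """Write result rows as TSV (floats at 6 significant digits, stable header).

    Permutation p-values are floored at 1/(B+1) by construction and never
    render as 0.
    """
    df = pd.DataFrame([vars(r) for r in rows], columns=_RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def write_vcf(region: GenotypeRegion, path: str | Path, chromosome: str = "1") -> None:
    """Write hard-call genotypes (rounded dosage) as a minimal VCFv4.2 file."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(region.samples) + "\n")
        for j in range(region.n_variants):
            calls = []
            for d in region.dosage[:, j]:
                calls.append("./." if np.isnan(d) else gt_map[int(round(d))])
            fh.write(
                f"{chromosome}\t{int(region.positions[j])}\t{region.variant_ids[j]}"
                f"\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_phenotypes(samples: list[str], trait: np.ndarray, path: str | Path,
                     trait_name: str = "trait") -> None:
    pd.DataFrame({"sample_id": samples, trait_name: trait}).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def trait_model_to_json(model: TraitModel) -> dict:
    """JSON-serialisable ground-truth sidecar for a simulated trait."""
    return {
        "causal_ids": list(model.causal_ids),
        "signs": model.signs.tolist(),
        "effect": model.effect,
        "residual_sd": model.residual_sd,
        "max_causal_maf": model.max_causal_maf,
        "total_causal_maf": model.total_causal_maf,
        "prop_risk": model.prop_risk,
        "variance_explained": model.variance_explained,
        "achieved_causal_maf": model.achieved_causal_maf,
    }
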