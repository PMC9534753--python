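"""Genotype matrix container and VCF 4.2 input/output.

Genotypes are stored as an individuals x sites int8 matrix of alternate-
allele dosages (0, 1, 2) with -1 for missing, alongside per-genotype
(ref, alt) read depths and per-individual population and region labels.
Sample names written to VCF are ``<region>_<population>_<index>`` so a
round trip preserves the labels; an explicit sample->population->region
table can override the encoding when reading external files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

REGION_A = "SMO"  # Sierra Madre Oriental
REGION_B = "ChD"  # Chihuahuan Desert

MISSING = -1


@dataclass
class GenotypeMatrix:
    genotypes: np.ndarray            # (n_ind, n_sites) int8, -1 = missing
    allele_depths: np.ndarray        # (n_ind, n_sites, 2) int32 (ref, alt)
    chrom: np.ndarray                # (n_sites,) contig names
    pos: np.ndarray                  # (n_sites,) 1-based positions
    pop_labels: list[str]
    region_labels: list[str]
    sample_names: list[str] = field(default=None)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.allele_depths = np.asarray(self.allele_depths, dtype=np.int32)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n_ind, n_sites = self.genotypes.shape
        if self.allele_depths.shape != (n_ind, n_sites, 2):
            raise ValueError("allele_depths shape mismatch")
        if len(self.chrom) != n_sites or len(self.pos) != n_sites:
            raise ValueError("site annotation length mismatch")
        if len(self.pop_labels) != n_ind or len(self.region_labels) != n_ind:
            raise ValueError("individual label length mismatch")
        if self.sample_names is None:
            counters: dict[str, int] = {}
            names = []
            for pop, reg in zip(self.pop_labels, self.region_labels):
                counters[pop] = counters.get(pop, 0) + 1
                names.append(f"{reg}_{pop}_{counters[pop]:03d}")
            self.sample_names = names
        elif len(self.sample_names) != n_ind:
            raise ValueError("sample_names length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def site_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    def region_order(self) -> list[str]:
        """Regions in canonical order (SMO first when present)."""
        seen = list(dict.fromkeys(self.region_labels))
        if set(seen) == {REGION_A, REGION_B}:
            return [REGION_A, REGION_B]
        return seen

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.pop_labels))

    def individual_index(self, pop: str | None = None,
                         region: str | None = None) -> np.ndarray:
        sel = np.ones(self.n_individuals, dtype=bool)
        if pop is not None:
            sel &= np.array([p == pop for p in self.pop_labels])
        if region is not None:
            sel &= np.array([r == region for r in self.region_labels])
        return np.nonzero(sel)[0]

    def called(self) -> np.ndarray:
        return self.genotypes != MISSING

    def missing_fraction(self) -> float:
        return float((self.genotypes == MISSING).mean()) if self.genotypes.size else 0.0

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype != bool:
            index = index.astype(np.int64)
        return GenotypeMatrix(
            self.genotypes[:, index], self.allele_depths[:, index],
            self.chrom[index], self.pos[index],
            list(self.pop_labels), list(self.region_labels),
            list(self.sample_names))

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype != bool:
            index = index.astype(np.int64)
        return GenotypeMatrix(
            self.genotypes[index], self.allele_depths[index],
            self.chrom, self.pos,
            [self.pop_labels[i] for i in index],
            [self.region_labels[i] for i in index],
            [self.sample_names[i] for i in index])

    def equal_calls(self, other: "GenotypeMatrix") -> bool:
        return (self.genotypes.shape == other.genotypes.shape
                and np.array_equal(self.genotypes, other.genotypes))


def _vcf_header(gm: GenotypeMatrix) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in dict.fromkeys(gm.chrom.tolist()):
        length = int(gm.pos[gm.chrom == contig].max()) + 1000
        header.contigs.add(str(contig), length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths for the ref and alt alleles")
    for name in gm.sample_names:
        header.add_sample(name)
    return header


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write genotypes with GT and AD FORMAT fields to an uncompressed VCF."""
    path = str(path)
    header = _vcf_header(gm)
    with pysam.VariantFile(path, "w", header=header) as out:
        for s in range(gm.n_sites):
            rec = out.new_record(contig=str(gm.chrom[s]),
                                 start=int(gm.pos[s]) - 1,
                                 alleles=("A", "T"), id=f"snp{s}")
            rec.filter.add("PASS")
            for i, name in enumerate(gm.sample_names):
                g = int(gm.genotypes[i, s])
                if g == MISSING:
                    rec.samples[name]["GT"] = (None, None)
                else:
                    rec.samples[name]["GT"] = (0, 1) if g == 1 else (g // 2, g // 2)
                rec.samples[name]["AD"] = (int(gm.allele_depths[i, s, 0]),
                                           int(gm.allele_depths[i, s, 1]))
            out.write(rec)


def _labels_from_name(name: str) -> tuple[str, str]:
    parts = name.split("_")
    if len(parts) >= 3:
        return parts[1], parts[0]  # (pop, region)
    return name, name


def read_vcf(path, pops: dict[str, tuple[str, str]] | None = None,
             drop_filtered: bool = True) -> GenotypeMatrix:
    """Read a multi-sample VCF with GT (and optionally AD) fields.

    ``pops`` maps sample name -> (population, region); when omitted the
    labels are decoded from ``<region>_<population>_<index>`` sample names.
    Sites with a non-PASS FILTER are dropped when drop_filtered is set
    (upstream caller annotations are honoured, never recomputed). Records
    with more than one alternate allele cannot be represented in a dosage
    matrix and are skipped; sites monomorphic in the sample are removed
    later by the biallelic filter.
    """
    genos, depths, chroms, positions = [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if drop_filtered and rec.filter.keys() not in ([], ["PASS"]):
                continue
            if rec.alts is not None and len(rec.alts) > 1:
                continue
            g_row = np.full(len(samples), MISSING, dtype=np.int8)
            d_row = np.zeros((len(samples), 2), dtype=np.int32)
            for i, name in enumerate(samples):
                call = rec.samples[name]
                gt = call.get("GT")
                if gt is not None and None not in gt:
                    g_row[i] = sum(1 for a in gt if a and a > 0)
                ad = call.get("AD")
                if ad is not None and ad[0] is not None:
                    d_row[i, 0] = ad[0]
                    d_row[i, 1] = ad[1] if len(ad) > 1 and ad[1] is not None else 0
            genos.append(g_row)
            depths.append(d_row)
            chroms.append(rec.contig)
            positions.append(rec.pos)
    if pops is not None:
        pop_labels = [pops[s][0] for s in samples]
        region_labels = [pops[s][1] for s in samples]
    else:
        decoded = [_labels_from_name(s) for s in samples]
        pop_labels = [p for p, _ in decoded]
        region_labels = [r for _, r in decoded]
    n_sites = len(genos)
    genotypes = (np.stack(genos, axis=1) if n_sites
                 else np.zeros((len(samples), 0), dtype=np.int8))
    allele_depths = (np.stack(depths, axis=1) if n_sites
                     else np.zeros((len(samples), 0, 2), dtype=np.int32))
    return GenotypeMatrix(genotypes, allele_depths,
                          np.array(chroms, dtype=object),
                          np.array(positions, dtype=np.int64),
                          pop_labels, region_labels, samples)


def read_pops_table(path) -> dict[str, tuple[str, str]]:
    """Read a sample<TAB>population<TAB>region table."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop, region = line.split("\t")[:3]
            out[sample] = (pop, region)
    return out
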