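"""SNP dosage matrix container and file round-trips.

The central genotype object is a genotypes x markers matrix of biallelic
minor-allele dosages in {0, 1, 2}, with missing calls stored as NaN.  This is
the layout produced by genotyping-by-sequencing (GBS) pipelines after SNP
calling, and the input expected by every downstream quality-control and
prediction step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

_VALID_DOSAGES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosage matrix (genotypes x markers).

    Parameters
    ----------
    genotype_ids
        Unique genotype (line / accession sample) identifiers, one per row.
    marker_ids
        Unique marker identifiers, one per column.
    dosage
        Float array of shape ``(n_genotypes, n_markers)`` with values in
        {0, 1, 2} and NaN for missing calls.  Dosage counts copies of the
        minor allele.
    chrom, pos
        Optional per-marker coordinates; carried as metadata only and never
        used in computation.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    cross_labels: list[str] | None = field(default=None, repr=False)
    accession_ids: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D array")
        n, m = self.dosage.shape
        if len(self.genotype_ids) != n:
            raise ValueError(
                f"{len(self.genotype_ids)} genotype ids for {n} dosage rows"
            )
        if len(self.marker_ids) != m:
            raise ValueError(
                f"{len(self.marker_ids)} marker ids for {m} dosage columns"
            )
        if len(set(self.genotype_ids)) != n:
            raise ValueError("genotype ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids are not unique")
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, _VALID_DOSAGES).all():
            bad = np.unique(observed[~np.isin(observed, _VALID_DOSAGES)])
            raise ValueError(f"dosage values outside {{0,1,2,NaN}}: {bad[:5]}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the call is missing."""
        return np.isnan(self.dosage)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            genotype_ids=list(self.genotype_ids),
            marker_ids=list(self.marker_ids),
            dosage=self.dosage.copy(),
            chrom=None if self.chrom is None else np.asarray(self.chrom).copy(),
            pos=None if self.pos is None else np.asarray(self.pos).copy(),
            cross_labels=None if self.cross_labels is None else list(self.cross_labels),
            accession_ids=None if self.accession_ids is None else list(self.accession_ids),
        )

    def subset(
        self,
        genotypes: np.ndarray | list | None = None,
        markers: np.ndarray | list | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given rows/columns.

        `genotypes` / `markers` may be boolean masks, integer indices, or
        lists of identifiers.
        """
        gi = self._resolve(genotypes, self.genotype_ids)
        mi = self._resolve(markers, self.marker_ids)
        out = GenotypeMatrix(
            genotype_ids=[self.genotype_ids[i] for i in gi],
            marker_ids=[self.marker_ids[j] for j in mi],
            dosage=self.dosage[np.ix_(gi, mi)],
            chrom=None if self.chrom is None else np.asarray(self.chrom)[mi],
            pos=None if self.pos is None else np.asarray(self.pos)[mi],
        )
        if self.cross_labels is not None:
            out.cross_labels = [self.cross_labels[i] for i in gi]
        if self.accession_ids is not None:
            out.accession_ids = [self.accession_ids[i] for i in gi]
        return out

    @staticmethod
    def _resolve(sel, ids: list[str]) -> np.ndarray:
        if sel is None:
            return np.arange(len(ids))
        sel = np.asarray(sel)
        if sel.dtype == bool:
            if sel.size != len(ids):
                raise ValueError("boolean selector length mismatch")
            return np.flatnonzero(sel)
        if sel.dtype.kind in "iu":
            return sel
        index = {g: i for i, g in enumerate(ids)}
        missing = [s for s in sel if s not in index]
        if missing:
            raise KeyError(f"identifiers not present: {missing[:5]}")
        return np.array([index[s] for s in sel])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.genotype_ids, columns=self.marker_ids
        )

    # -- delimited matrix round-trip ---------------------------------------

    def write_matrix(self, path, sep: str = "\t") -> None:
        """Write as a delimited genotypes x markers table (NaN left empty)."""
        self.to_dataframe().to_csv(path, sep=sep, index_label="genotype")

    @classmethod
    def read_matrix(cls, path, sep: str = "\t") -> "GenotypeMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.empty and df.columns.empty:
            raise ValueError(f"empty genotype matrix file: {path}")
        values = df.to_numpy(dtype=float)
        # anything outside the dosage domain is treated as a missing call
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(values) & ~np.isin(values, _VALID_DOSAGES)
        values[bad] = np.nan
        return cls(
            genotype_ids=[str(g) for g in df.index],
            marker_ids=[str(m) for m in df.columns],
            dosage=values,
        )

    # -- minimal VCF round-trip (GT field only) ----------------------------

    def write_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with GT-only genotype columns.

        Alleles are written as REF=A, ALT=T placeholders; dosage d maps to
        the unphased genotype with d ALT alleles, NaN to ``./.``.
        """
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        chrom = self.chrom if self.chrom is not None else ["1"] * self.n_markers
        pos = self.pos if self.pos is not None else np.arange(1, self.n_markers + 1)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.genotype_ids)
                + "\n"
            )
            for j, mid in enumerate(self.marker_ids):
                calls = [
                    gt_map.get(d, "./.") if not np.isnan(d) else "./."
                    for d in self.dosage[:, j]
                ]
                fh.write(
                    f"{chrom[j]}\t{int(pos[j])}\t{mid}\tA\tT\t.\t.\t.\tGT\t"
                    + "\t".join(calls)
                    + "\n"
                )

    @classmethod
    def read_vcf(cls, path) -> "GenotypeMatrix":
        """Read a VCF with diploid GT fields into ALT-allele dosages.

        Only the GT subfield is interpreted; any call with a missing allele
        becomes NaN.
        """
        genotype_ids: list[str] = []
        marker_ids: list[str] = []
        chrom: list[str] = []
        pos: list[int] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    fields = line.split("\t")
                    if len(fields) < 10:
                        raise ValueError(f"line {lineno}: VCF has no sample columns")
                    genotype_ids = fields[9:]
                    continue
                if not genotype_ids:
                    raise ValueError(f"line {lineno}: record before #CHROM header")
                fields = line.split("\t")
                if len(fields) != 9 + len(genotype_ids):
                    raise ValueError(
                        f"line {lineno}: expected {9 + len(genotype_ids)} columns, "
                        f"got {len(fields)}"
                    )
                fmt = fields[8].split(":")
                if "GT" not in fmt:
                    raise ValueError(f"line {lineno}: record lacks GT field")
                gt_idx = fmt.index("GT")
                chrom.append(fields[0])
                pos.append(int(fields[1]))
                marker_ids.append(
                    fields[2] if fields[2] != "." else f"{fields[0]}_{fields[1]}"
                )
                row = []
                for sample in fields[9:]:
                    gt = sample.split(":")[gt_idx].replace("|", "/")
                    alleles = gt.split("/")
                    if "." in alleles or len(alleles) != 2:
                        row.append(np.nan)
                    else:
                        row.append(float(int(alleles[0]) + int(alleles[1])))
                rows.append(row)
        if not rows:
            raise ValueError(f"empty VCF (no variant records): {path}")
        return cls(
            genotype_ids=genotype_ids,
            marker_ids=marker_ids,
            dosage=np.array(rows, dtype=float).T,
            chrom=np.array(chrom),
            pos=np.array(pos),
        )

    # -- HapMap-like layout -------------------------------------------------

    @classmethod
    def read_hapmap(cls, path, sep: str = "\t") -> "GenotypeMatrix":
        """Read a HapMap-like table (markers as rows, IUPAC diploid calls).

        Expected columns: ``rs#, alleles, chrom, pos`` followed by one column
        per genotype with two-letter calls (e.g. ``AA``, ``AT``); ``NN`` or
        ``--`` is missing.  Dosage counts the second allele of the
        ``alleles`` field (e.g. ``A/T`` -> copies of T).
        """
        df = pd.read_csv(path, sep=sep, dtype=str)
        required = {"rs#", "alleles", "chrom", "pos"}
        if not required.issubset(df.columns):
            raise ValueError(f"HapMap file lacks columns {required - set(df.columns)}")
        sample_cols = [c for c in df.columns if c not in required]
        if not sample_cols or df.empty:
            raise ValueError(f"empty HapMap file: {path}")
        dosage = np.full((len(sample_cols), len(df)), np.nan)
        for j, (_, rec) in enumerate(df.iterrows()):
            ref, alt = rec["alleles"].split("/")
            for i, col in enumerate(sample_cols):
                call = rec[col]
                if not isinstance(call, str) or len(call) != 2 or call in ("NN", "--"):
                    continue
                if set(call) - {ref, alt}:
                    continue  # unknown allele -> missing
                dosage[i, j] = call.count(alt)
        return cls(
            genotype_ids=sample_cols,
            marker_ids=list(df["rs#"]),
            dosage=dosage,
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(dtype=int),
        )
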