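"""CSV readers/writers for cohort tables and pipeline outputs.

Schemas (RFC-4180 CSV, UTF-8, "." decimal, "NA" for the only permitted
missing value — genotype):

* ``cohort.csv`` — sample_id, cohort, steatosis_grade, steatosis_binary,
  genotype (CC/CG/GG/NA);
* ``phenome.csv`` — sample_id + one column per clinical variable;
* ``proteome.csv`` — sample_id + one positive numeric column per protein;
* ``truth.json`` — planted-signal metadata sidecar.

Numerics are written with 12 significant digits so round-trips preserve
test precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .simulate import SyntheticCohort

__all__ = ["write_cohort", "read_cohort", "CohortFiles", "JoinReport"]

_FLOAT_FMT = "%.12g"
_GENO_SYMBOLS = {"CC", "CG", "GG", "NA"}


@dataclass
class CohortFiles:
    cohort: Path
    phenome: Path
    proteome: Path
    truth: Path | None = None


@dataclass
class JoinReport:
    n_joined: int
    dropped: dict[str, list[str]]  # file -> sample_ids absent from the join


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> CohortFiles:
    """Write a generated cohort to ``outdir`` (cohort/phenome/proteome/truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = CohortFiles(
        cohort=outdir / "cohort.csv",
        phenome=outdir / "phenome.csv",
        proteome=outdir / "proteome.csv",
        truth=outdir / "truth.json",
    )
    pd.DataFrame(
        {
            "sample_id": cohort.sample_id,
            "cohort": cohort.cohort,
            "steatosis_grade": cohort.steatosis_grade,
            "steatosis_binary": cohort.steatosis_binary,
            "genotype": cohort.genotype_symbols(),
        }
    ).to_csv(files.cohort, index=False)
    ph = pd.DataFrame(cohort.phenome, columns=cohort.pheno_names)
    ph.insert(0, "sample_id", cohort.sample_id)
    ph.to_csv(files.phenome, index=False, float_format=_FLOAT_FMT)
    pr = pd.DataFrame(cohort.proteome, columns=cohort.protein_names)
    pr.insert(0, "sample_id", cohort.sample_id)
    pr.to_csv(files.proteome, index=False, float_format=_FLOAT_FMT)
    files.truth.write_text(json.dumps(cohort.truth, indent=1))
    return files


def read_cohort(files: CohortFiles) -> tuple[SyntheticCohort, JoinReport]:
    """Read and inner-join the cohort tables on sample_id.

    Validates: unique sample_ids per file, genotype symbols in
    {CC, CG, GG, NA}, numeric strictly-positive proteome cells.  Samples
    missing from any file are dropped and reported.
    """
    # "NA" is a genotype symbol here, not a pandas missing value
    meta = pd.read_csv(
        files.cohort,
        dtype={"sample_id": str, "genotype": str},
        keep_default_na=False,
    )
    ph = pd.read_csv(files.phenome, dtype={"sample_id": str})
    pr = pd.read_csv(files.proteome, dtype={"sample_id": str})

    for name, df in (("cohort", meta), ("phenome", ph), ("proteome", pr)):
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicated sample_id in {name}.csv: {sorted(set(dup))}")

    bad = set(meta["genotype"]) - _GENO_SYMBOLS
    if bad:
        rows = meta.index[meta["genotype"].isin(bad)].tolist()
        raise ValueError(
            f"unknown genotype symbol(s) {sorted(bad)} in cohort.csv rows {rows}"
        )

    prot_cols = [c for c in pr.columns if c != "sample_id"]
    vals = pr[prot_cols].to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        for c in prot_cols:
            col = pd.to_numeric(pr[c], errors="coerce")
            if col.isna().any():
                row = int(col.index[col.isna()][0])
                raise ValueError(f"non-numeric proteome cell at row {row}, column {c}")
        vals = pr[prot_cols].apply(pd.to_numeric).to_numpy()
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        i, j = np.argwhere(~(np.isfinite(vals) & (vals > 0)))[0]
        raise ValueError(
            f"proteome cell must be positive and finite: row {i}, column {prot_cols[j]}"
        )

    ids = [set(df["sample_id"]) for df in (meta, ph, pr)]
    common = ids[0] & ids[1] & ids[2]
    report = JoinReport(
        n_joined=len(common),
        dropped={
            name: sorted(s - common)
            for name, s in zip(("cohort", "phenome", "proteome"), ids)
            if s - common
        },
    )
    meta = meta[meta["sample_id"].isin(common)].sort_values("sample_id")
    ph = ph[ph["sample_id"].isin(common)].sort_values("sample_id")
    pr = pr[pr["sample_id"].isin(common)].sort_values("sample_id")

    geno_num = meta["genotype"].map({"CC": 0, "CG": 1, "GG": 2, "NA": -1}).to_numpy()
    truth = json.loads(files.truth.read_text()) if files.truth and files.truth.exists() else {}
    pheno_names = [c for c in ph.columns if c != "sample_id"]
    cohort = SyntheticCohort(
        sample_id=meta["sample_id"].to_numpy(),
        cohort=meta["cohort"].to_numpy(),
        genotype=geno_num,
        steatosis_grade=meta["steatosis_grade"].to_numpy(),
        steatosis_binary=meta["steatosis_binary"].to_numpy(),
        phenome=ph[pheno_names].to_numpy(dtype=float),
        pheno_names=pheno_names,
        proteome=pr[prot_cols].to_numpy(dtype=float),
        protein_names=prot_cols,
        truth=truth,
        config=SimulationConfig(
            n_total=len(common),
            discovery_n=min(
                max(int((meta["cohort"] == "discovery").sum()), 1), len(common) - 1
            ),
            genotype_missing_n=int((geno_num == -1).sum()),
            n_proteins=len(prot_cols),
            n_pheno=len(pheno_names),
            signal_proteins=(),
            signal_pheno=(),
        ),
    )
    return cohort, report
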