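"""Readers and writers for the on-disk formats.

Genotypes come either as a TSV (header row of SNP ids, first column of
individual ids, cells in {0,1,2,NA}) or a PLINK BED/BIM/FAM triplet.
Phenotypes, weights and covariates are TSV tables keyed by individual id;
pedigrees are 3-column TSV (id, sire, dam) with 0 or empty for an unknown
parent. All outputs are TSV plus a machine-readable run-metadata JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import plink
from .datamodel import GenotypeMatrix, standardize_genotypes

log = logging.getLogger("hybbr")

MISSING_TOKENS = {"", ".", "NA", "nan", "NaN"}


def read_genotypes(path, fmt: str = "tsv", freq=None) -> GenotypeMatrix:
    """Read dosages from TSV or a PLINK prefix and standardize them."""
    if fmt == "plink":
        dosage, bim, fam = plink.read_bed(path)
        return standardize_genotypes(dosage, freq=freq,
                                     snp_ids=bim["snp_id"].to_numpy(),
                                     individual_ids=fam["iid"].to_numpy())
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
                     keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate individual ids in {path}: {dups}")
    raw = df.to_numpy(dtype=float)
    return standardize_genotypes(raw, freq=freq,
                                 snp_ids=df.columns.to_numpy(),
                                 individual_ids=df.index.astype(str).to_numpy())


def write_genotypes_tsv(path, geno: GenotypeMatrix) -> None:
    df = pd.DataFrame(geno.raw, index=geno.individual_ids, columns=geno.snp_ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_table(path, id_col: str = "id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={id_col: str},
                     na_values=list(MISSING_TOKENS), keep_default_na=False)
    if df[id_col].duplicated().any():
        dups = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"id present twice in {path}: {dups}")
    return df.set_index(id_col)


def read_tables(genotype_ids, phenotypes=None, pedigree=None, weights=None,
                covariates=None):
    """Load the record tables and inner-join them against the genotyped ids.

    Extra records are dropped with a log line; a missing weights table
    defaults every record weight to 1.0.
    """
    genotype_ids = [str(x) for x in genotype_ids]
    out = {"ids": genotype_ids}
    if phenotypes is not None:
        ph = read_table(phenotypes)
        extra = ph.index.difference(genotype_ids)
        if len(extra):
            log.info("dropping %d phenotype records without genotypes", len(extra))
        missing = [i for i in genotype_ids if i not in ph.index]
        if missing:
            raise ValueError(f"genotyped ids without phenotype: {missing[:5]}...")
        out["phenotypes"] = ph.loc[genotype_ids]
    if weights is not None:
        wt = read_table(weights)
        out["weights"] = wt.reindex(genotype_ids).iloc[:, 0].fillna(1.0).to_numpy()
    else:
        out["weights"] = np.ones(len(genotype_ids))
    if covariates is not None:
        cov = read_table(covariates)
        out["covariates"] = cov.loc[[i for i in genotype_ids if i in cov.index]]
    if pedigree is not None:
        ped = pd.read_csv(pedigree, sep="\t", dtype=str,
                          na_values=list(MISSING_TOKENS), keep_default_na=False)
        ped.columns = [c.lower() for c in ped.columns[:3]] + list(ped.columns[3:])
        out["pedigree"] = ped
    return out


def write_outputs(out_dir, summary, report=None, trace=None, config=None,
                  seed=None, snp_ids=None, positions=None, gebv=None,
                  gebv_ids=None) -> dict:
    """Write snp_effects.tsv, gebv.tsv, trace.tsv and report.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = len(summary.g_mean)
    snp_ids = np.array([f"snp{j}" for j in range(m)]) if snp_ids is None else snp_ids
    positions = np.arange(m) if positions is None else positions
    eff = pd.DataFrame({
        "snp_id": snp_ids,
        "position": positions,
        "mean_effect": summary.g_mean,
        "P1": summary.P_mean[:, 0], "P2": summary.P_mean[:, 1],
        "P3": summary.P_mean[:, 2], "P4": summary.P_mean[:, 3],
        "pip": summary.pip,
        "active": summary.active.astype(int),
    })
    eff.to_csv(out_dir / "snp_effects.tsv", sep="\t", index=False)
    written = {"snp_effects": str(out_dir / "snp_effects.tsv")}
    if gebv is not None:
        ids = (np.arange(len(gebv)) if gebv_ids is None else gebv_ids)
        pd.DataFrame({"id": ids, "gebv": gebv}).to_csv(
            out_dir / "gebv.tsv", sep="\t", index=False)
        written["gebv"] = str(out_dir / "gebv.tsv")
    if trace is not None and len(trace.sigma_e2):
        tr = pd.DataFrame({
            "iteration": np.arange(1, len(trace.sigma_e2) + 1),
            "sigma_e2": trace.sigma_e2, "sigma_a2": trace.sigma_a2,
            "Pr1": trace.Pr[:, 0], "Pr2": trace.Pr[:, 1],
            "Pr3": trace.Pr[:, 2], "Pr4": trace.Pr[:, 3],
            "n1": trace.counts[:, 0], "n2": trace.counts[:, 1],
            "n3": trace.counts[:, 2], "n4": trace.counts[:, 3],
        })
        tr.to_csv(out_dir / "trace.tsv", sep="\t", index=False)
        written["trace"] = str(out_dir / "trace.tsv")
    import hybbr

    meta = {
        "accuracy": getattr(report, "accuracy", None) if report else None,
        "bias": getattr(report, "bias", None) if report else None,
        "auc": getattr(report, "auc", None) if report else None,
        "component_counts": summary.component_counts.tolist(),
        "Pr_mean": summary.Pr_mean.tolist(),
        "sigma_e2_mean": summary.sigma_e2_mean,
        "n_iter": summary.n_iter,
        "seed": seed,
        "config": config,
        "versions": {"hybbr": hybbr.__version__, "numpy": np.__version__},
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    written["report"] = str(out_dir / "report.json")
    return written
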