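"""Minimal PLINK 1 BED/BIM/FAM codec (SNP-major, BED v1.0).

Dosages are counts of the A1 allele: two-bit codes 00 -> 2, 10 -> 1,
11 -> 0, 01 -> missing (NaN). Only reading and writing of complete
triplets is supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit code -> dosage of A1
_CODE_TO_DOSE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def read_bed(prefix) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read ``prefix``.bed/.bim/.fam; returns (dosage n x m, bim, fam)."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"snp_id": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    n, m = len(fam), len(bim)
    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:3] != _MAGIC:
        raise ValueError(
            f"{prefix}.bed: bad magic bytes {data[:3].hex()} (want {_MAGIC.hex()}: "
            "BED v1.0 SNP-major)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(data) != expected:
        raise ValueError(f"{prefix}.bed: {len(data)} bytes, expected {expected}")
    body = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack two-bit fields, lowest bits first
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    dosage = _CODE_TO_DOSE[codes[:, :n]].T.copy()
    return dosage, bim, fam


def write_bed(prefix, dosage, snp_ids=None, individual_ids=None,
              chrom=None, pos=None) -> None:
    """Write a BED/BIM/FAM triplet from an n x m dosage matrix."""
    prefix = Path(prefix)
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    snp_ids = [f"snp{j}" for j in range(m)] if snp_ids is None else list(snp_ids)
    individual_ids = ([f"id{j}" for j in range(n)] if individual_ids is None
                      else list(individual_ids))
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) if pos is None else np.asarray(pos)

    codes = np.full(dosage.shape, 0b01, dtype=np.uint8)  # missing
    for dose, code in _DOSE_TO_CODE.items():
        codes[dosage == dose] = code
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    body = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        body |= padded[:, shift::4] << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(body.tobytes())
    bim = pd.DataFrame({"chrom": chrom, "snp_id": snp_ids, "cm": 0,
                        "pos": pos, "a1": "A", "a2": "B"})
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({"fid": individual_ids, "iid": individual_ids,
                        "father": 0, "mother": 0, "sex": 0, "pheno": -9})
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
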