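"""File round-trips and run configuration.

Formats are deliberately plain: pedigree and phenotype tables as headed CSV,
genotypes as a whitespace/CSV 0-1-2 matrix with the animal id in the first
column, covariance matrices as whitespace-separated symmetric text matrices,
and the run configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic import MarkerMatrix
from .pedigree import Pedigree
from .solver import DEFAULT_TOL

logger = logging.getLogger("sstblup")

FORMULATIONS = ("H", "Htilde", "Psi")


@dataclass
class RunConfig:
    """Paths and knobs for one evaluation run."""

    pedigree: str = "pedigree.csv"
    genotypes: str = "genotypes.txt"
    phenotypes: str = "phenotypes.csv"
    genetic_covariance: str = "G0.txt"
    residual_covariance: str = "R0.txt"
    formulation: str = "Psi"
    gamma: float = 0.95
    lam: float = 0.05
    tol: float = DEFAULT_TOL
    max_iter: int | None = None
    seed: int = 0
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(
                f"formulation must be one of {FORMULATIONS}, got {self.formulation!r}"
            )
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lambda must be in (0, 1], got {self.lam}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s) {sorted(bad)} in {path}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    if not required <= set(df.columns):
        raise ValueError(f"pedigree file needs columns {sorted(required)}")
    return Pedigree(list(df[["animal", "sire", "dam"]].itertuples(index=False, name=None)))


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    pd.DataFrame(ped.records, columns=["animal", "sire", "dam"]).to_csv(path, index=False)


def read_genotypes(path: str | Path, allele_freq_path: str | Path | None = None) -> MarkerMatrix:
    """012 matrix, animal id in the first column, whitespace or comma separated."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    ids = df.iloc[:, 0].astype(str).str.strip().tolist()
    counts = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    freq = None
    if allele_freq_path is not None:
        sidecar = pd.read_csv(allele_freq_path)
        freq = sidecar["freq"].to_numpy(dtype=float)
    return MarkerMatrix(counts=counts, ids=ids, allele_freq=freq)


def write_genotypes(counts: np.ndarray, ids: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for animal, row in zip(ids, np.asarray(counts)):
            fh.write(animal + " " + " ".join(str(int(v)) for v in row) + "\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"animal", "trait", "value", "fixed_level"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype file needs columns {sorted(required)}")
    return df


def write_phenotypes(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, index=False)


def read_covariance(path: str | Path) -> np.ndarray:
    mat = np.atleast_2d(np.loadtxt(path))
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{path} is not a symmetric square matrix")
    return mat


def write_covariance(mat: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mat, dtype=float), fmt="%.10g")


def write_solutions(ebv: pd.DataFrame, path: str | Path) -> None:
    ebv.to_csv(path, index=False, float_format="%.10g")


def write_trace(trace: list[float], path: str | Path) -> None:
    pd.DataFrame({"iteration": range(len(trace)), "criterion": trace}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, seed: int, files: list[str | Path]) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "seed": seed,
        "files": {Path(f).name: sha256_file(f) for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def verify_manifest(out_dir: str | Path) -> bool:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        if sha256_file(out_dir / name) != digest:
            return False
    return True
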