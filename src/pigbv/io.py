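"""File formats and run configuration.

All tables are delimited text. Dialects:

* pedigree: CSV ``animal,sire,dam,cohort,litter,sex``; ``0`` or empty
  field means unknown parent/litter.
* phenotypes: CSV ``animal,cohort,batch,litter,sex,<trait...>``; ``NA``
  marks a missing record.
* genotypes: either the project tabular CSV (``animal`` column followed
  by one column per marker, dosages in {0,1,2} or NA) or a PLINK-raw
  style dialect (whitespace-separated, header
  ``FID IID PAT MAT SEX PHENOTYPE <marker>_<allele> ...``); the reader
  auto-detects the dialect from the header.
* marker calls: CSV ``animal,SCD,LEPR`` with genotype-class strings
  (e.g. ``TT/TC/CC``) or NA.
* EBV tables: CSV ``animal,trait,ebv,method,scenario``.
* reports: TSV grid plus a JSON document.

Every writer puts a ``# pigbv seed=<seed> config=<hash>`` comment on the
first line when run metadata is supplied; readers skip ``#`` lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluate import EvaluationReport
from .pedigree import UNKNOWN, Pedigree, PedigreeRecord
from .simulate import QUALITY_TRAITS, GenotypeMatrix, ScenarioConfig


class FileFormatError(ValueError):
    pass


#: Genotype-class strings per major marker, indexed by alternative-allele dosage.
MARKER_CLASS_STRINGS: dict[str, tuple[str, str, str]] = {
    "SCD": ("TT", "TC", "CC"),
    "LEPR": ("CC", "CT", "TT"),
}


def _header_comment(seed: int | None, config_hash: str | None) -> str | None:
    if seed is None and config_hash is None:
        return None
    return f"# pigbv seed={seed} config={config_hash or 'n/a'}"


def _open_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [l.rstrip("\n") for l in fh]


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def write_pedigree(
    ped: Pedigree, path: str | Path, seed: int | None = None, config_hash: str | None = None
) -> None:
    with open(path, "w") as fh:
        hc = _header_comment(seed, config_hash)
        if hc:
            fh.write(hc + "\n")
        fh.write("animal,sire,dam,cohort,litter,sex\n")
        for r in ped.records:
            fh.write(f"{r.animal},{r.sire},{r.dam},{r.cohort},{r.litter},{r.sex}\n")


def read_pedigree(path: str | Path) -> Pedigree:
    lines = [l for l in _open_lines(path) if l and not l.startswith("#")]
    header = lines[0].split(",")
    if header[:6] != ["animal", "sire", "dam", "cohort", "litter", "sex"]:
        raise FileFormatError(f"{path}: unexpected pedigree header {header}")
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 6:
            raise FileFormatError(f"{path}:{ln}: expected 6 fields, got {len(parts)}")
        animal, sire, dam, cohort, litter, sex = parts
        try:
            cohort_i = int(cohort)
        except ValueError as exc:
            raise FileFormatError(f"{path}:{ln}: cohort {cohort!r} not an integer") from exc
        records.append(
            PedigreeRecord(
                animal, sire or UNKNOWN, dam or UNKNOWN, cohort_i, litter or UNKNOWN, sex
            )
        )
    return Pedigree(records)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(
    pheno: pd.DataFrame, path: str | Path, seed: int | None = None, config_hash: str | None = None
) -> None:
    with open(path, "w") as fh:
        hc = _header_comment(seed, config_hash)
        if hc:
            fh.write(hc + "\n")
        pheno.to_csv(fh, na_rep="NA", index_label="animal")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", na_values=["NA"], index_col="animal")
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# Genotypes (project tabular and PLINK-raw style)
# ---------------------------------------------------------------------------

def write_genotypes(
    geno: GenotypeMatrix,
    path: str | Path,
    dialect: str = "tabular",
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    D = geno.dosages

    def fmt(v: float) -> str:
        if np.isnan(v):
            return "NA"
        if float(v) != int(v):
            raise FileFormatError("cannot write fractional (imputed) dosages")
        return str(int(v))

    with open(path, "w") as fh:
        hc = _header_comment(seed, config_hash)
        if hc and dialect == "tabular":
            fh.write(hc + "\n")
        if dialect == "tabular":
            fh.write("animal," + ",".join(geno.marker_ids) + "\n")
            for i, a in enumerate(geno.animal_ids):
                fh.write(a + "," + ",".join(fmt(v) for v in D[i]) + "\n")
        elif dialect == "plink-raw":
            snps = " ".join(f"{m}_A" for m in geno.marker_ids)
            fh.write(f"FID IID PAT MAT SEX PHENOTYPE {snps}\n")
            for i, a in enumerate(geno.animal_ids):
                row = " ".join(fmt(v) for v in D[i])
                fh.write(f"0 {a} 0 0 0 -9 {row}\n")
        else:
            raise FileFormatError(f"unknown genotype dialect {dialect!r}")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read either dialect; auto-detected from the header line."""
    lines = [l for l in _open_lines(path) if l and not l.startswith("#")]
    header = lines[0]
    if header.startswith("FID IID"):
        toks = header.split()
        marker_ids = [t.rsplit("_", 1)[0] for t in toks[6:]]
        animal_col, first_dose, sep = 1, 6, None
    elif header.startswith("animal"):
        toks = header.split(",")
        marker_ids = toks[1:]
        animal_col, first_dose, sep = 0, 1, ","
    else:
        raise FileFormatError(f"{path}: unrecognized genotype header")
    animals: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split(sep)
        if len(parts) != first_dose + len(marker_ids):
            raise FileFormatError(
                f"{path}:{ln}: expected {first_dose + len(marker_ids)} fields, got {len(parts)}"
            )
        animals.append(parts[animal_col])
        row: list[float] = []
        for mj, tok in enumerate(parts[first_dose:]):
            if tok == "NA":
                row.append(np.nan)
            elif tok in ("0", "1", "2"):
                row.append(float(tok))
            else:
                raise FileFormatError(
                    f"{path}:{ln}: dosage {tok!r} for {marker_ids[mj]} not in {{0,1,2,NA}}"
                )
        rows.append(row)
    D = np.array(rows, dtype=float)
    counts = (~np.isnan(D)).sum(axis=0)
    sums = np.nansum(D, axis=0)
    freq = np.divide(sums, 2.0 * counts, out=np.full(D.shape[1], np.nan),
                     where=counts > 0)
    meta = pd.DataFrame(
        {
            "allele_freq": freq,
            "is_major": [m in MARKER_CLASS_STRINGS for m in marker_ids],
            "label": [m if m in MARKER_CLASS_STRINGS else "chip" for m in marker_ids],
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    return GenotypeMatrix(animals, marker_ids, D, meta)


# ---------------------------------------------------------------------------
# Major-marker calls
# ---------------------------------------------------------------------------

def write_marker_calls(
    calls: pd.DataFrame, path: str | Path, seed: int | None = None, config_hash: str | None = None
) -> None:
    markers = list(calls.columns)
    with open(path, "w") as fh:
        hc = _header_comment(seed, config_hash)
        if hc:
            fh.write(hc + "\n")
        fh.write("animal," + ",".join(markers) + "\n")
        for a, row in calls.iterrows():
            cells = []
            for m in markers:
                v = row[m]
                if pd.isna(v):
                    cells.append("NA")
                else:
                    cells.append(MARKER_CLASS_STRINGS[m][int(v)])
            fh.write(f"{a}," + ",".join(cells) + "\n")


def read_marker_calls(path: str | Path) -> pd.DataFrame:
    lines = [l for l in _open_lines(path) if l and not l.startswith("#")]
    header = lines[0].split(",")
    markers = header[1:]
    inv = {
        m: {s: d for d, s in enumerate(MARKER_CLASS_STRINGS[m])} for m in markers
    }
    animals, rows = [], []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != len(header):
            raise FileFormatError(f"{path}:{ln}: expected {len(header)} fields")
        animals.append(parts[0])
        row = []
        for m, tok in zip(markers, parts[1:]):
            if tok == "NA":
                row.append(np.nan)
            elif tok in inv[m]:
                row.append(float(inv[m][tok]))
            else:
                raise FileFormatError(f"{path}:{ln}: unknown {m} class {tok!r}")
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(animals, name="animal"), columns=markers)


# ---------------------------------------------------------------------------
# EBV tables and reports
# ---------------------------------------------------------------------------

def write_ebv_table(
    estimates: Sequence, path: str | Path, seed: int | None = None, config_hash: str | None = None
) -> None:
    """One row per animal x trait, with method/scenario columns."""
    rows = []
    for est in estimates:
        for t in est.ebv.columns:
            for a, v in est.ebv[t].items():
                rows.append((a, t, v, est.method, est.scenario))
    df = pd.DataFrame(rows, columns=["animal", "trait", "ebv", "method", "scenario"])
    with open(path, "w") as fh:
        hc = _header_comment(seed, config_hash)
        if hc:
            fh.write(hc + "\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def read_ebv_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df["animal"] = df["animal"].astype(str)
    return df


def write_report(
    report: EvaluationReport,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    with open(tsv_path, "w") as fh:
        hc = _header_comment(seed, config_hash)
        if hc:
            fh.write(hc + "\n")
        report.correlations.to_csv(fh, sep="\t", na_rep="NA", index_label="method")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=1)


def read_report(tsv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", comment="#", index_col="method")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class BayesBSettings:
    pi_chip: float = 0.95
    pi_major: float = 0.0
    chain_length: int = 20_000
    burn_in: int = 5_000
    thinning: int = 10
    nu: float = 4.2
    h2_prior: float = 0.5
    min_maf: float = 0.05
    min_call_rate: float = 0.95


@dataclass
class RunConfig:
    seed: int
    output_dir: str = "pigbv_out"
    replicates: int = 1
    traits: list[str] = field(default_factory=lambda: list(QUALITY_TRAITS))
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    bayesb: BayesBSettings = field(default_factory=BayesBSettings)
    h2_override: dict[str, float] = field(default_factory=dict)
    verbosity: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _from_mapping(cls, data: Mapping, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise FileFormatError(f"unknown config keys in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise FileFormatError("config must set a seed (stochastic stages require it)")
    nested = dict(raw)
    scenario = _from_mapping(ScenarioConfig, nested.pop("scenario", {}), "scenario")
    bayesb = _from_mapping(BayesBSettings, nested.pop("bayesb", {}), "bayesb")
    cfg = _from_mapping(RunConfig, nested, "top level")
    cfg.scenario = scenario
    cfg.bayesb = bayesb
    return cfg
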