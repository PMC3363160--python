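"""File formats, run configuration and the end-to-end pipeline.

All on-disk formats are plain TSV/JSON: pedigree (id, sire, dam,
generation; 0 = unknown parent), SNP map (snp_id, chrom, pos_morgan),
dosage matrix (first column id, one header column per snp_id, cells in
{0, 1, 2, NA}), phenotypes (id, y with NA for missing, tbv), SNP effects,
GEBV (id, gebv, pev), architecture JSON and a run manifest JSON recording
the config snapshot, per-stage seeds, file checksums and wall-clock times
needed to re-run any stage bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import concordance, evaluate_method
from .kinship import blup_solve, compute_grm, compute_nrm, reml_fit
from .qtl_scan import effect_profile, grammar_scan
from .simulate import (GenomeMap, Pedigree, SimParams, SimulatedDataset,
                       TraitArchitecture, simulate_dataset)
from .wgr import (METHODS, ChainConfig, PosteriorSummary, PriorSpec,
                  SnpEffectVector, run_chain)

__all__ = [
    "DosageData",
    "RunConfig",
    "RunManifest",
    "GenotypeParseError",
    "read_pedigree", "write_pedigree",
    "read_map", "write_map",
    "read_genotypes", "write_dosages",
    "read_phenotypes", "write_phenotypes",
    "read_architecture", "write_architecture",
    "write_gebv", "read_gebv",
    "write_effects", "read_effects",
    "write_dataset",
    "run_pipeline",
    "get_logger",
]

log = logging.getLogger("gsbench")


def get_logger(level: str = "INFO") -> logging.Logger:
    """Stage-tagged stderr logger shared by the CLI and the pipeline."""
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s gsbench[%(stage)s] %(message)s",
                                         defaults={"stage": "-"}))
        log.addHandler(h)
    log.setLevel(level.upper())
    return log


class GenotypeParseError(ValueError):
    """Malformed genotype file; carries 1-based row/column coordinates."""


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_pedigree(path, pedigree: Pedigree) -> None:
    pd.DataFrame({"id": pedigree.ids, "sire": pedigree.sire, "dam": pedigree.dam,
                  "generation": pedigree.generation}).to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t")
    return Pedigree(ids=df["id"].to_numpy(), sire=df["sire"].to_numpy(),
                    dam=df["dam"].to_numpy(),
                    generation=df["generation"].to_numpy(dtype=object))


def write_map(path, gmap: GenomeMap) -> None:
    pd.DataFrame({"snp_id": gmap.snp_id, "chrom": gmap.chrom,
                  "pos_morgan": gmap.pos}).to_csv(path, sep="\t", index=False)


def read_map(path, chrom_lengths: Optional[dict] = None) -> GenomeMap:
    df = pd.read_csv(path, sep="\t")
    return GenomeMap(df["snp_id"].to_numpy(dtype=object), df["chrom"].to_numpy(),
                     df["pos_morgan"].to_numpy(), chrom_lengths or {})


def write_dosages(path, ids: np.ndarray, snp_id: np.ndarray, Z: np.ndarray) -> None:
    df = pd.DataFrame(Z, columns=list(snp_id))
    df.insert(0, "id", ids)
    out = df.to_csv(sep="\t", index=False, na_rep="NA", float_format="%.0f")
    Path(path).write_text(out)


@dataclass
class DosageData:
    """Dosage matrix with ids, marker names and (optionally) an aligned map."""

    ids: np.ndarray
    snp_id: np.ndarray
    Z: np.ndarray                 # float, NaN = missing
    gmap: Optional[GenomeMap] = None

    @property
    def missingness(self) -> np.ndarray:
        return np.isnan(self.Z).mean(axis=0)


def read_genotypes(path, map_path=None) -> DosageData:
    """Read a dosage TSV, validating every cell is 0/1/2 or NA.

    A malformed cell raises :class:`GenotypeParseError` naming its 1-based
    data row and column. With ``map_path`` the map is read and aligned to
    the matrix columns (same markers, map order).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if "id" not in df.columns:
        raise GenotypeParseError("missing 'id' header column")
    snp_id = np.array(df.columns[1:], dtype=object)
    body = df.iloc[:, 1:]
    was_na = body.isna().to_numpy()
    Z = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.isnan(Z) & ~was_na
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise GenotypeParseError(
            f"non-numeric dosage at row {r + 1}, column {c + 1}: "
            f"{body.iat[r, c]!r}")
    bad = np.isfinite(Z) & ~np.isin(Z, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise GenotypeParseError(
            f"dosage outside {{0,1,2}} at row {r + 1}, column {c + 1}: "
            f"{body.iat[r, c]!r}")
    ids = df["id"].astype(np.int64).to_numpy()
    gmap = None
    if map_path is not None:
        gmap = read_map(map_path)
        if list(gmap.snp_id) != list(snp_id):
            raise GenotypeParseError("map and dosage matrix list different markers")
    return DosageData(ids=ids, snp_id=snp_id, Z=Z, gmap=gmap)


def write_phenotypes(path, ids, y, tbv) -> None:
    pd.DataFrame({"id": ids, "y": y, "tbv": tbv}).to_csv(
        path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_architecture(path, arch: TraitArchitecture) -> None:
    Path(path).write_text(json.dumps(arch.to_json_dict(), indent=1))


def read_architecture(path) -> TraitArchitecture:
    return TraitArchitecture.from_json_dict(json.loads(Path(path).read_text()))


def write_gebv(path, ids, gebv, pev) -> None:
    pd.DataFrame({"id": ids, "gebv": gebv, "pev": pev}).to_csv(
        path, sep="\t", index=False)


def read_gebv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_effects(path, snp_id, beta, inclusion_prob=None) -> None:
    d = {"snp_id": snp_id, "beta": beta}
    if inclusion_prob is not None:
        d["inclusion_prob"] = inclusion_prob
    pd.DataFrame(d).to_csv(path, sep="\t", index=False)


def read_effects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dataset(out_dir, ds: SimulatedDataset) -> dict:
    """Write a simulated dataset as the standard TSV/JSON file set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in [
        ("pedigree", "pedigree.tsv"), ("map", "map.tsv"),
        ("genotypes", "genotypes.tsv"), ("phenotypes", "phenotypes.tsv"),
        ("architecture", "architecture.json"), ("metadata", "simulation_meta.json")]}
    write_pedigree(paths["pedigree"], ds.pedigree)
    write_map(paths["map"], ds.markers.gmap)
    write_dosages(paths["genotypes"], ds.markers.ids, ds.markers.gmap.snp_id,
                  ds.marker_dosages)
    write_phenotypes(paths["phenotypes"], ds.phenotypes.ids, ds.phenotypes.y,
                     ds.phenotypes.tbv)
    write_architecture(paths["architecture"], ds.arch)
    paths["metadata"].write_text(json.dumps(
        {"seed": ds.seed, "params": ds.params.to_dict(), "version": __version__},
        indent=1))
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _hyper(v):
    """Parse 'estimate' / number for a hyperparameter field."""
    if v is None or (isinstance(v, str) and v.lower() == "estimate"):
        return None
    return float(v)


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults reproduce the study-scale run.

    ``df``, ``pi`` and ``sigma2_snp`` accept a number or the string
    "estimate". Unknown keys in a config file are rejected.
    """

    sim: SimParams = field(default_factory=SimParams)
    methods: list = field(default_factory=lambda: list(METHODS))
    df: Optional[float] = None            # None = estimate
    pi: Optional[float] = None
    sigma2_snp: Optional[float] = None
    lambda_: Optional[float] = None
    burn_in: int = 10000
    n_samples: int = 10000
    thin: int = 20
    df_estimation_multiplier: int = 5
    evaluation_set: str = "all_offspring"   # or "unphenotyped", "phenotyped"
    scan_kinship: str = "pedigree"          # or "genomic"
    master_seed: int = 0
    output_dir: str = "gsbench_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.evaluation_set not in ("all_offspring", "unphenotyped", "phenotyped"):
            raise ValueError(f"unknown evaluation_set {self.evaluation_set!r}")
        if self.scan_kinship not in ("pedigree", "genomic"):
            raise ValueError(f"unknown scan_kinship {self.scan_kinship!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_d = d.pop("sim", {})
        known_sim = {f.name for f in fields(SimParams)}
        bad = set(sim_d) - known_sim
        if bad:
            raise ValueError(f"unknown sim config keys: {sorted(bad)}")
        known = {f.name for f in fields(cls)} - {"sim"}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for k in ("df", "pi", "sigma2_snp", "lambda_"):
            if k in d:
                d[k] = _hyper(d[k])
        return cls(sim=SimParams(**sim_d), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def chain_config(self, seed: int) -> ChainConfig:
        return ChainConfig(burn_in=self.burn_in, n_samples=self.n_samples,
                           thin=self.thin,
                           df_estimation_multiplier=self.df_estimation_multiplier,
                           seed=seed)

    def prior_for(self, method: str) -> PriorSpec:
        kw: dict = {"lambda_": self.lambda_}
        if method in ("bayesa", "bbt"):
            kw["df"] = self.df
        if method in ("bbn", "bbt"):
            kw["pi_"] = self.pi
        if method == "bbn":
            kw["sigma2_snp"] = self.sigma2_snp
        return PriorSpec(method, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d


@dataclass
class RunManifest:
    """Record of a pipeline run: everything needed to re-run it bit-identically."""

    config: dict
    version: str
    stage_seeds: dict
    stages: list = field(default_factory=list)   # name, wall_s, outputs+checksums
    completed: bool = False

    def add_stage(self, name: str, wall_s: float, outputs: dict) -> None:
        self.stages.append({
            "name": name, "wall_seconds": round(wall_s, 3),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                        for k, p in outputs.items()},
        })

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=1))
        tmp.replace(path)            # atomic on POSIX


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage_seeds(master_seed: int, methods: list) -> dict:
    names = ["simulate"] + [f"wgr_{m}" for m in methods]
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate -> pedigree BLUP -> GBLUP -> regression methods ->
    evaluation -> association scan, writing every artefact under
    ``config.output_dir`` and a manifest at each stage boundary."""
    logger = get_logger(config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.master_seed, config.methods)
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           stage_seeds=seeds)
    mpath = out / "manifest.json"

    def done(name: str, t0: float, outputs: dict) -> None:
        manifest.add_stage(name, time.time() - t0, outputs)
        manifest.write(mpath)
        logger.info("stage complete (%.1fs)", time.time() - t0,
                    extra={"stage": name})

    # -- simulate
    t0 = time.time()
    ds = simulate_dataset(config.sim, seed=seeds["simulate"])
    paths = write_dataset(out, ds)
    done("simulate", t0, paths)

    ped = ds.pedigree
    y = ds.phenotypes.y
    off = ~ped.is_founder
    if config.evaluation_set == "all_offspring":
        eval_rows = np.flatnonzero(off)
    elif config.evaluation_set == "unphenotyped":
        eval_rows = np.flatnonzero(off & ~ds.phenotypes.phenotyped_mask)
    else:
        eval_rows = np.flatnonzero(off & ds.phenotypes.phenotyped_mask)
    tbv_eval = ds.phenotypes.tbv[eval_rows]

    gebv_store: dict[str, np.ndarray] = {}
    reports = []

    # -- pedigree BLUP baseline
    t0 = time.time()
    A = compute_nrm(ped)
    vc_a = reml_fit(y, A)
    fit_a = blup_solve(y, A, vc_a)
    p = out / "gebv_pblup.tsv"
    write_gebv(p, ped.ids, fit_a.gebv, fit_a.pev)
    gebv_store["pblup"] = fit_a.gebv
    r_blup = float(np.corrcoef(tbv_eval, fit_a.gebv[eval_rows])[0, 1])
    done("pblup", t0, {"gebv": p, "varcomp": _write_vc(out / "varcomp_pblup.json", vc_a)})

    # -- GBLUP
    t0 = time.time()
    Z = ds.marker_dosages
    G = compute_grm(Z, ids=ped.ids)
    vc_g = reml_fit(y, G)
    fit_g = blup_solve(y, G, vc_g)
    p = out / "gebv_gblup.tsv"
    write_gebv(p, ped.ids, fit_g.gebv, fit_g.pev)
    gebv_store["gblup"] = fit_g.gebv
    reports.append(evaluate_method("gblup", tbv_eval, fit_g.gebv[eval_rows],
                                   pev=fit_g.pev[eval_rows],
                                   sigma2_e_hat=vc_g.sigma2_e, r_blup=r_blup))
    done("gblup", t0, {"gebv": p, "varcomp": _write_vc(out / "varcomp_gblup.json", vc_g)})

    # -- whole-genome regression methods
    for m in config.methods:
        t0 = time.time()
        prior = config.prior_for(m)
        cc = config.chain_config(seeds[f"wgr_{m}"])
        res = run_chain(y, Z, prior, cc, snp_id=ds.markers.gmap.snp_id, ids=ped.ids)
        pg = out / f"gebv_{m}.tsv"
        pe = out / f"effects_{m}.tsv"
        ph = out / f"hyper_{m}.json"
        write_gebv(pg, ped.ids, res.gebv, res.pev)
        write_effects(pe, res.snp_effects.snp_id, res.snp_effects.beta,
                      res.snp_effects.inclusion_prob)
        ph.write_text(json.dumps(
            {"hyper_estimates": res.hyper_estimates,
             "mu_hat": res.mu_hat, "sigma2_e_hat": res.sigma2_e_hat,
             "schedule": res.diagnostics["schedule"],
             "df_acceptance_rate": res.diagnostics["df_acceptance_rate"],
             "traces": {k: np.asarray(v).tolist()
                        for k, v in res.diagnostics["traces"].items()}}))
        gebv_store[m] = res.gebv
        reports.append(evaluate_method(m, tbv_eval, res.gebv[eval_rows],
                                       pev=res.pev[eval_rows],
                                       sigma2_e_hat=res.sigma2_e_hat, r_blup=r_blup))
        done(f"wgr_{m}", t0, {"gebv": pg, "effects": pe, "hyper": ph})

    # -- evaluation
    t0 = time.time()
    conc = concordance({k: v[eval_rows] for k, v in gebv_store.items()})
    rep = {
        "evaluation_set": config.evaluation_set,
        "pedigree_blup_accuracy": r_blup,
        "table": [r.to_dict() for r in reports],
        "concordance": {"methods": conc.methods,
                        "correlations": conc.correlations.tolist(),
                        "min": conc.min_offdiag, "max": conc.max_offdiag},
    }
    p = out / "report.json"
    p.write_text(json.dumps(rep, indent=1))
    done("evaluate", t0, {"report": p})

    # -- association scan
    t0 = time.time()
    Kscan = A if config.scan_kinship == "pedigree" else G
    scan = grammar_scan(y, Kscan, Z, ds.markers.gmap)
    p = out / "scan.tsv"
    pd.DataFrame({"snp_id": scan.snp_id, "chrom": scan.chrom, "pos": scan.pos,
                  "beta_scan": scan.beta_scan, "p_value": scan.p_value,
                  "tested": scan.tested}).to_csv(p, sep="\t", index=False)
    prof_paths = {}
    for m in config.methods:
        eff = read_effects(out / f"effects_{m}.tsv")
        prof = effect_profile(
            SnpEffectVector(snp_id=eff["snp_id"].to_numpy(dtype=object),
                            beta=eff["beta"].to_numpy()),
            ds.markers.gmap)
        pp = out / f"profile_{m}.tsv"
        pd.DataFrame({"snp_id": prof.snp_id, "pos": prof.pos,
                      "abs_effect_proportion": prof.abs_effect_proportion}
                     ).to_csv(pp, sep="\t", index=False)
        prof_paths[f"profile_{m}"] = pp
    done("scan", t0, {"scan": p, **prof_paths})

    manifest.completed = True
    manifest.write(mpath)
    return manifest


def _write_vc(path, vc) -> Path:
    Path(path).write_text(json.dumps(
        {"sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e, "h2": vc.h2,
         "log_likelihood": vc.log_likelihood}))
    return Path(path)
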