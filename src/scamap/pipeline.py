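"""End-to-end orchestration: MSA assembly -> SCA -> sectors -> structure maps.

A single :class:`PipelineConfig` carries every threshold and file path; a run
executes the stages in order, writes TSV/JSON outputs plus the resolved
config next to them, and caches each stage by a content hash of its inputs
and parameters, so an MSA rebuild does not force structure recomputation and
vice versa.  Runs are deterministic given (inputs, config, seed): all
floating-point tables are written with a fixed format, so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from . import alignment as aln_mod
from . import sca as sca_mod
from . import structure as struct_mod
from . import synthetic as syn_mod

logger = logging.getLogger("scamap.pipeline")

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All knobs of the analysis in one place.

    File inputs are optional: with ``synthetic=True`` the MSA and structures
    are generated by the synthetic module (seeded); without structure inputs
    the structural stages are skipped with a notice.
    """

    output_dir: str = "scamap_out"
    seed: int = 1

    # --- MSA assembly
    synthetic: bool = False
    alignment_path: str | None = None
    alignment_format: str = "fasta"
    reference_id: str | None = None
    redundancy_cutoff: float | None = 0.90
    final_identity_cutoff: float | None = 0.95
    min_occupancy: float | None = 0.50

    # --- SCA
    pseudocount: float = 0.03
    neighbor_identity: float = 0.8
    n_null: int = 100
    null_percentile: float = 95.0
    n_components: int | None = None
    include_first_mode: bool = True
    sector_sd: float = 2.0
    ica_tol: float = 1e-8
    ica_max_iter: int = 1000

    # --- structures
    structure_paths: list[str] = field(default_factory=list)
    structure_pairs: list[list[str]] = field(default_factory=list)  # names for RMSD
    chain: str = "A"
    probe_radius: float = 1.4
    cavity_grid: float = 0.5
    lining_cutoff: float = 4.5
    burial_threshold: float = 0.25
    conserved_quantile: float = 0.8
    domain_partition: dict | None = None
    sites_of_interest: dict[str, list[float]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        for name, lo, hi in (
            ("redundancy_cutoff", 0.0, 1.0),
            ("final_identity_cutoff", 0.0, 1.0),
            ("min_occupancy", 0.0, 1.0),
            ("pseudocount", 0.0, 1.0),
            ("neighbor_identity", 0.0, 1.0),
            ("burial_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if v is not None and not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.cavity_grid > self.probe_radius:
            raise ValueError("cavity_grid must not exceed probe_radius")


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Stage:
    """Content-hash cache marker around one pipeline stage."""

    def __init__(self, out_dir: Path, name: str, key: dict):
        self.dir = out_dir
        self.name = name
        self.key = _hash(key)
        self.marker = out_dir / f".{name}.hash"

    def is_cached(self, outputs: list[Path]) -> bool:
        return (
            self.marker.exists()
            and self.marker.read_text().strip() == self.key
            and all(p.exists() for p in outputs)
        )

    def mark(self) -> None:
        self.marker.write_text(self.key)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dictionary.

    Any stage failure raises with the stage name; outputs of completed
    stages are kept.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    report: dict = {"seed": config.seed, "stages": []}
    stage = "build-msa"
    try:
        alignment, refmap = _stage_msa(config, out)
        report["stages"].append(stage)
        report["n_sequences"] = alignment.n_seq
        report["n_positions"] = alignment.n_cols

        stage = "sca"
        results = _stage_sca(config, out, alignment, refmap)
        report["stages"].append(stage)
        report["k_significant"] = int(results.k_significant)
        report["sectors"] = {s.label: len(s) for s in results.sectors}

        stage = "map-structure"
        if config.synthetic or config.structure_paths:
            struct_report = _stage_structures(config, out, results, refmap)
            report["stages"].append(stage)
            report["structure"] = struct_report
        else:
            logger.info("no structure inputs; structural stages skipped")
            report["structure_skipped"] = True
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# stages


def _msa_key(config: PipelineConfig) -> dict:
    return {
        "seed": config.seed,
        "synthetic": config.synthetic,
        "path": config.alignment_path and _file_hash(Path(config.alignment_path)),
        "format": config.alignment_format,
        "ref": config.reference_id,
        "final": config.final_identity_cutoff,
        "occ": config.min_occupancy,
    }


def _stage_msa(config: PipelineConfig, out: Path):
    st = _Stage(out, "msa", _msa_key(config))
    msa_path = out / "final_msa.fasta"
    refmap_path = out / "refmap.json"
    if st.is_cached([msa_path, refmap_path]):
        logger.info("build-msa: cached")
        alignment = aln_mod.read_alignment(msa_path)
        meta = json.loads(refmap_path.read_text())
        refmap = (
            aln_mod.ReferenceMap(
                meta["ref_id"], {int(k): v for k, v in meta["map"].items()}
            )
            if meta
            else None
        )
        return alignment, refmap

    if config.synthetic:
        spec = syn_mod.SyntheticMSASpec(seed=config.seed)
        alignment, truth = syn_mod.gen_sector_msa(spec)
        truth_df = pd.DataFrame(
            [
                {"sector": k + 1, "column": c}
                for k, cols in enumerate(truth.sector_positions)
                for c in cols
            ]
        )
        _write_tsv(truth_df, out / "planted_truth.tsv")
    else:
        if config.alignment_path is None:
            raise ValueError("alignment_path required unless synthetic=True")
        alignment = aln_mod.read_alignment(
            config.alignment_path, config.alignment_format
        )
    if config.final_identity_cutoff is not None:
        alignment = aln_mod.redundancy_filter(alignment, config.final_identity_cutoff)
    refmap = None
    if config.reference_id is not None:
        alignment, refmap = aln_mod.truncate_to_reference(
            alignment, config.reference_id
        )
    elif config.min_occupancy is not None:
        alignment = aln_mod.truncate_by_occupancy(alignment, config.min_occupancy)
    aln_mod.write_alignment(alignment, msa_path)
    refmap_path.write_text(
        json.dumps(
            {"ref_id": refmap.ref_id, "map": refmap.col_to_resnum} if refmap else None
        )
    )
    st.mark()
    return alignment, refmap


def _sca_key(config: PipelineConfig, out: Path) -> dict:
    return {
        "msa": _file_hash(out / "final_msa.fasta"),
        "lam": config.pseudocount,
        "nbr": config.neighbor_identity,
        "n_null": config.n_null,
        "pct": config.null_percentile,
        "k": config.n_components,
        "first": config.include_first_mode,
        "sd": config.sector_sd,
        "seed": config.seed,
        "ica": [config.ica_tol, config.ica_max_iter],
    }


_SCA_OUTPUTS = [
    "conservation.tsv",
    "eigenvalues.tsv",
    "sectors.tsv",
    "coupling_matrix.tsv",
    "sca_summary.txt",
]


def _stage_sca(config: PipelineConfig, out: Path, alignment, refmap):
    st = _Stage(out, "sca", _sca_key(config, out))
    outputs = [out / f for f in _SCA_OUTPUTS]
    if st.is_cached(outputs):
        logger.info("sca: cached")
        return _load_sca_results(out)

    model = sca_mod.SCA(
        alignment,
        refmap=refmap,
        neighbor_identity=config.neighbor_identity,
        pseudocount=config.pseudocount,
    )
    results = model.fit(
        n_null=config.n_null,
        percentile=config.null_percentile,
        seed=config.seed,
        n_components=config.n_components,
        include_first_mode=config.include_first_mode,
        sector_sd=config.sector_sd,
        ica_tol=config.ica_tol,
        ica_max_iter=config.ica_max_iter,
    )
    _write_tsv(results.conservation.to_frame(refmap), out / "conservation.tsv")
    _write_tsv(results.eigenvalue_table(), out / "eigenvalues.tsv")
    _write_tsv(results.sectors.to_frame(), out / "sectors.tsv")
    np.savetxt(
        out / "coupling_matrix.tsv",
        results.coupling_matrix,
        delimiter="\t",
        fmt=_FLOAT_FMT,
    )
    (out / "sca_summary.txt").write_text(results.summary() + "\n")
    st.mark()
    return results


def _load_sca_results(out: Path) -> SimpleNamespace:
    """Reload a cached SCA stage into the light view downstream stages use."""
    sectors_df = pd.read_csv(out / "sectors.tsv", sep="\t")
    sectors = []
    if len(sectors_df):
        for label, grp in sectors_df.groupby("sector", sort=True):
            positions = tuple(int(x) for x in grp["refnum"])
            loadings = dict(zip(positions, grp["loading"].astype(float)))
            comp = int(str(label).rsplit("_", 1)[1]) - 1
            sectors.append(sca_mod.Sector(str(label), positions, loadings, comp))
    ev = pd.read_csv(out / "eigenvalues.tsv", sep="\t")
    cons = pd.read_csv(out / "conservation.tsv", sep="\t")
    return SimpleNamespace(
        sectors=sca_mod.SectorSet(sectors, "cached"),
        k_significant=int(ev["significant"].sum()),
        conservation=sca_mod.ConservationProfile(cons["D"].to_numpy()),
    )


def _stage_structures(config: PipelineConfig, out: Path, results, refmap) -> dict:
    partition = (
        struct_mod.DomainPartition.from_dict(config.domain_partition)
        if config.domain_partition
        else None
    )
    structures: dict[str, struct_mod.StructureModel] = {}
    if config.synthetic:
        for kind in ("hollow-shell", "globule"):
            s, _truth = syn_mod.gen_toy_structure(
                syn_mod.SyntheticStructureSpec(kind=kind, seed=config.seed)
            )
            structures[kind] = s
            struct_mod.write_structure(s, out / f"{kind}.pdb")
    for path in config.structure_paths:
        structures[Path(path).stem] = struct_mod.read_structure(path)

    rep: dict = {}
    for name, s in structures.items():
        entry: dict = {}
        sasa = struct_mod.compute_sasa(
            s, probe=config.probe_radius, burial_threshold=config.burial_threshold
        )
        _write_tsv(sasa.per_residue.reset_index(), out / f"{name}_sasa.tsv")
        entry["n_residues"] = len(sasa.per_residue)
        entry["buried_fraction"] = float(sasa.per_residue["buried"].mean())

        cavities = struct_mod.detect_cavities(
            s,
            grid=config.cavity_grid,
            probe=config.probe_radius,
            lining_cutoff=config.lining_cutoff,
        )
        _write_tsv(cavities.to_frame(), out / f"{name}_cavities.tsv")
        entry["n_cavities"] = len(cavities)
        if len(cavities):
            entry["largest_cavity_A3"] = cavities.cavities[0].volume

        if partition is not None:
            _write_tsv(
                struct_mod.bfactor_summary(s, partition), out / f"{name}_bfactor.tsv"
            )
            _write_tsv(
                struct_mod.rama_fractions(s, partition), out / f"{name}_rama.tsv"
            )
        for site, xyz in config.sites_of_interest.items():
            entry[f"depth_{site}"] = struct_mod.site_depth(
                s, xyz, grid=config.cavity_grid, probe=config.probe_radius
            )

        # sector-on-structure report where sector positions resolve
        known = {r for _, r, _ in sasa.per_residue.index}
        if any(p in known for sec in results.sectors for p in sec.positions):
            annot = struct_mod.annotate_sectors(
                results.sectors,
                refmap,
                s,
                sasa,
                conservation=results.conservation,
                cavities=cavities,
                partition=partition,
                chain=config.chain,
                conserved_quantile=config.conserved_quantile,
            )
            annot["pairwise_overlap"] = {
                f"{a}->{b}": v for (a, b), v in annot["pairwise_overlap"].items()
            }
            entry["sector_report"] = annot
            scores = {
                (config.chain, p): sec.loadings[p]
                for sec in results.sectors
                for p in sec.positions
            }
            struct_mod.write_bfactor_annotated(
                s, scores, out / f"{name}_sector_loadings.pdb"
            )
        rep[name] = entry

    for pair in config.structure_pairs:
        a, b = pair
        prof = struct_mod.per_residue_rmsd(structures[a], structures[b])
        _write_tsv(prof.to_frame(), out / f"rmsd_{a}_vs_{b}.tsv")
        rep[f"rmsd_{a}_vs_{b}"] = prof.global_rmsd
    return rep
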