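"""Pipeline orchestration: fit -> LRT -> FdNs -> structural projection.

A single structured YAML config drives the chain; every stage writes its
table (TSV/JSON) into the output directory as soon as it completes, so
partial results survive a downstream failure.  The run report echoes the
config, package version, seeds and input digests, and collects warnings;
the exit status of the CLI wrapper is nonzero iff any stage errored.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .branch_site import fit_model_A, lrt, neb_sites
from .fdns import CladeSpec, detect_fdns, records_to_frame, summarize_by_branch
from .likelihood import BranchSiteEngine
from .ocr import OCRPlate, derive_metrics
from .seqio import GeneticCode, read_codon_alignment
from .structure import (
    ResidueMapping,
    proximity_report,
    read_channel_annotation,
    read_structure,
)
from .trees import Phylogeny

logger = logging.getLogger(__name__)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    seed: int = 0
    input_digests: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "input_digests": self.input_digests,
                    "stages": self.stages,
                    "warnings": self.warnings,
                    "errors": self.errors,
                },
                fh,
                indent=2,
                default=str,
            )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for key in ("alignment", "tree"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    return cfg


def run_pipeline(config_path, out_dir=None) -> RunReport:
    """Execute fit -> LRT (Bonferroni over branches) -> FdNs -> structure.

    Branches listed under ``branches`` (label -> taxon list) are tested in
    turn by remarking the tree; the Bonferroni multiplier defaults to the
    number of branches tested.  FdNs scanning runs for every branch whose
    adjusted p-value is below 0.05 (configurable via ``fdns.all_branches``).
    """
    cfg = load_config(config_path)
    report = RunReport(config=cfg, seed=int(cfg.get("seed", 0)))
    out = Path(out_dir or cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    code = GeneticCode.from_table_id(int(cfg.get("code_table", 5)))
    aln = read_codon_alignment(cfg["alignment"], code)
    phylo = Phylogeny.from_file(cfg["tree"])
    for key in ("alignment", "tree"):
        report.input_digests[key] = _digest(cfg[key])

    branches = {
        label: frozenset(taxa) for label, taxa in (cfg.get("branches") or {}).items()
    }
    n_tests = int(cfg.get("n_tests") or max(len(branches), 1))
    df = int(cfg.get("df", 2))
    seed = int(cfg.get("seed", 0))

    # stage 1: branch-site LRT per branch
    lrt_rows, significant = [], []
    try:
        for label, taxa in branches.items():
            marked = phylo.copy()
            marked.mark_clade(set(taxa))
            engine = BranchSiteEngine(
                aln, marked, freq_scheme=cfg.get("freq_scheme", "F3x4")
            )
            null = fit_model_A(
                aln, marked, fix_omega2=True, seed=seed, engine=engine,
                n_starts=int(cfg.get("n_starts", 3)),
            )
            alt = fit_model_A(
                aln, marked, fix_omega2=False, seed=seed, init=null, engine=engine,
                n_starts=int(cfg.get("n_starts", 3)),
            )
            res = lrt(null, alt, df=df, n_tests=n_tests)
            sites = neb_sites(aln, marked, alt, engine=engine)
            lrt_rows.append(
                {
                    "branch": label,
                    "lnL_null": null.lnL,
                    "lnL_alt": alt.lnL,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                    "n_tests": res.n_tests,
                    "kappa": alt.kappa,
                    "omega0": alt.omega0,
                    "omega2": alt.omega2,
                    "p0": alt.p0,
                    "p1": alt.p1,
                    "neb_sites": ",".join(map(str, sites.selected_sites)),
                }
            )
            if res.p_adjusted < 0.05:
                significant.append(label)
        lrt_cols = [
            "branch", "lnL_null", "lnL_alt", "statistic", "df", "p_raw",
            "p_adjusted", "n_tests", "kappa", "omega0", "omega2", "p0", "p1",
            "neb_sites",
        ]
        pd.DataFrame(lrt_rows, columns=lrt_cols).to_csv(
            out / "lrt.tsv", sep="\t", index=False
        )
        report.stages["lrt"] = {
            "table": str(out / "lrt.tsv"),
            "n_branches": len(branches),
            "significant": significant,
        }
    except Exception as exc:  # persist partial results, record, continue
        logger.exception("LRT stage failed")
        report.errors.append(f"lrt: {exc}")
        if lrt_rows:
            pd.DataFrame(lrt_rows).to_csv(out / "lrt.tsv", sep="\t", index=False)

    # stage 2: FdNs scan
    fdns_records = []
    fdns_cfg = cfg.get("fdns") or {}
    scan_branches = (
        list(branches) if fdns_cfg.get("all_branches") else significant
    ) if branches else []
    try:
        for label in scan_branches:
            clade = CladeSpec(label, branches[label])
            fdns_records += detect_fdns(
                aln, phylo, clade,
                require_absent_in_outgroups=bool(
                    fdns_cfg.get("require_absent_in_outgroups", False)
                ),
            )
        records_to_frame(fdns_records).to_csv(out / "fdns.tsv", sep="\t", index=False)
        summarize_by_branch(fdns_records).to_csv(
            out / "fdns_summary.tsv", sep="\t", index=False
        )
        report.stages["fdns"] = {
            "table": str(out / "fdns.tsv"),
            "n_records": len(fdns_records),
            "branches": scan_branches,
        }
    except Exception as exc:
        logger.exception("FdNs stage failed")
        report.errors.append(f"fdns: {exc}")

    # stage 3: structural projection of FdNs sites
    struct_cfg = cfg.get("structure") or {}
    if struct_cfg:
        try:
            model = read_structure(struct_cfg["pdb"])
            report.input_digests["structure"] = _digest(struct_cfg["pdb"])
            channels = read_channel_annotation(struct_cfg["channels"])
            chain = struct_cfg.get("chain", "A")
            mapping = None
            template_seq = struct_cfg.get("template_sequence")
            if template_seq:
                mapping = ResidueMapping.from_sequences(
                    template_seq, model.chain_sequence(chain)
                )
            residues = [(chain, r.site) for r in fdns_records] or [
                (chain, int(x)) for x in struct_cfg.get("residues", [])
            ]
            t4, t13 = (float(x) for x in struct_cfg.get("thresholds", (4.0, 13.0)))
            recs = proximity_report(
                model, residues, channels, mapping, within4=t4, within13=t13
            )
            pd.DataFrame(
                [
                    {
                        "chain": r.residue[0],
                        "residue": r.residue[1],
                        **{f"d_{p}": d for p, d in r.distances.items()},
                        "class": r.proximity_class,
                    }
                    for r in recs
                ]
            ).to_csv(out / "proximity.tsv", sep="\t", index=False)
            report.stages["structure"] = {
                "table": str(out / "proximity.tsv"),
                "n_residues": len(recs),
            }
        except Exception as exc:
            logger.exception("structure stage failed")
            report.errors.append(f"structure: {exc}")

    # stage 4: OCR metrics
    ocr_cfg = cfg.get("ocr") or {}
    if ocr_cfg:
        try:
            plate = OCRPlate.from_csv(ocr_cfg["wells"], ocr_cfg["measurements"])
            metrics = derive_metrics(
                plate, species_window=ocr_cfg.get("species_window", "mephisto")
            )
            payload = {
                "basal": metrics.basal,
                "maximal": metrics.maximal,
                "spare": metrics.spare,
                "untreated": metrics.untreated,
                "non_mitochondrial": metrics.non_mitochondrial,
                "response_window": list(metrics.response_window),
            }
            with open(out / "ocr_metrics.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            report.warnings += metrics.warnings
            report.stages["ocr"] = payload
        except Exception as exc:
            logger.exception("OCR stage failed")
            report.errors.append(f"ocr: {exc}")

    report.write(out / "report.json")
    return report
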