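"""End-to-end orchestration: mine -> mass-match -> phylo -> AU ->
reconcile -> rates, driven by one validated config mapping.

The pipeline is a pure function of (inputs, config, seeds) up to
timestamps; every stage logs its parameters and seed into the report.
"""

from __future__ import annotations

import json
import time
from pathlib import Path


from . import au_test, msdin_miner, peptide_chem, phylo, rates, reconcile, seqio

__all__ = ["PipelineConfigError", "validate_config", "run_pipeline"]

_STAGES = ("mine", "mass_match", "phylo", "au", "reconcile", "rates")


class PipelineConfigError(ValueError):
    """All schema violations, reported together."""


_SCHEMA = {
    "mine": {"fasta": str, "train_fasta": str, "leader_len": int,
             "min_aa": int, "max_aa": int, "intron_len": list},
    "mass_match": {"peaks": str, "tol_ppm": (int, float), "adduct": str,
                   "modset": str},
    "phylo": {"aln": str, "model": str, "alpha": (int, float),
              "p_inv": (int, float)},
    "au": {"trees": str, "B": int, "seed": int},
    "reconcile": {"gene_tree": str, "species_tree": str, "map": str,
                  "costs": list},
    "rates": {"loci": dict, "genus_map": dict, "reference": str},
}


def validate_config(config: dict) -> list[str]:
    """Return every schema violation at once (empty list = valid)."""
    errors = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    for stage, block in config.items():
        if stage in ("outdir", "seed"):
            continue
        if stage not in _SCHEMA:
            errors.append(f"unknown stage {stage!r}")
            continue
        if not isinstance(block, dict):
            errors.append(f"stage {stage!r} must be a mapping")
            continue
        for key, val in block.items():
            if key not in _SCHEMA[stage]:
                errors.append(f"{stage}.{key}: unknown key")
            elif not isinstance(val, _SCHEMA[stage][key]):
                errors.append(
                    f"{stage}.{key}: expected "
                    f"{_SCHEMA[stage][key]}, got {type(val).__name__}")
    return errors


def _require_file(path, stage):
    if not Path(path).exists():
        raise FileNotFoundError(f"stage {stage!r}: input file {path} not found")
    return path


def run_pipeline(config: dict) -> dict:
    """Run the configured stages in dependency order; returns the report."""
    errors = validate_config(config)
    if errors:
        raise PipelineConfigError("; ".join(errors))
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed, "stages": {}, "started": time.time()}

    hits = []
    if "mine" in config:
        blk = config["mine"]
        contigs = seqio.read_fasta(_require_file(blk["fasta"], "mine"))
        train = [r.residues for r in seqio.read_fasta(
            _require_file(blk["train_fasta"], "mine"))]
        profile = msdin_miner.build_leader_profile(
            train, blk.get("leader_len", 9))
        for contig in contigs:
            hits.extend(msdin_miner.scan_orfs(
                contig, profile,
                min_aa=blk.get("min_aa", 25), max_aa=blk.get("max_aa", 45),
                intron_len=tuple(blk.get("intron_len", (40, 200)))))
        report["stages"]["mine"] = {
            "params": {k: v for k, v in blk.items()},
            "n_hits": len(hits),
            "hits": [
                {"contig": h.gene_model.interval.contig,
                 "span": [h.gene_model.interval.start,
                          h.gene_model.interval.end],
                 "strand": h.gene_model.interval.strand,
                 "core": h.precursor.core if h.precursor else None,
                 "score": round(h.score, 3)}
                for h in hits],
            "distance": msdin_miner.toxin_gene_distance(hits),
        }

    if "mass_match" in config:
        blk = config["mass_match"]
        peaks = seqio.read_peak_table(_require_file(blk["peaks"], "mass_match"))
        modset = peptide_chem.PRESET_MODS[blk.get("modset", "amatoxin")]
        candidates = {}
        for h in hits:
            if h.precursor is None:
                continue
            f = modset.apply(peptide_chem.peptide_formula(
                h.precursor.core, "cyclic"))
            candidates[h.precursor.core] = peptide_chem.adduct_mz(
                peptide_chem.monoisotopic_mass(f),
                blk.get("adduct", "M+H"))
        matches = peptide_chem.match_peaks(
            peaks, candidates, tol=blk.get("tol_ppm", 10.0))
        report["stages"]["mass_match"] = {
            "params": {k: v for k, v in blk.items()},
            "candidates": candidates,
            "matches": [m.__dict__ for m in matches],
        }

    fitted_tree = None
    aln = None
    params = None
    if "phylo" in config:
        blk = config["phylo"]
        aln = seqio.read_alignment(_require_file(blk["aln"], "phylo"))
        params = phylo.empirical_params(
            aln, alpha=blk.get("alpha", 1.0), p_inv=blk.get("p_inv", 0.0))
        dm = phylo.nucleotide_distance(aln, "JC")
        start = phylo.nj_tree(dm)
        fitted_tree, lnl = phylo.nni_search(aln, start, params)
        report["stages"]["phylo"] = {
            "params": {k: v for k, v in blk.items()},
            "lnl": lnl,
            "tree": seqio.write_newick(fitted_tree),
        }

    if "au" in config:
        blk = config["au"]
        if aln is None or params is None:
            raise PipelineConfigError("au stage requires the phylo stage")
        text = Path(_require_file(blk["trees"], "au")).read_text()
        trees = [seqio.parse_newick(ln) for ln in text.splitlines()
                 if ln.strip()]
        result = au_test.au_table(
            aln, trees, params, B=blk.get("B", 10_000),
            seed=blk.get("seed", seed))
        report["stages"]["au"] = {
            "params": {k: v for k, v in blk.items()},
            "table": [r.as_dict() for r in result.rows],
        }

    if "reconcile" in config:
        blk = config["reconcile"]
        gt = seqio.parse_newick(
            Path(_require_file(blk["gene_tree"], "reconcile")).read_text())
        st = seqio.parse_newick(
            Path(_require_file(blk["species_tree"], "reconcile")).read_text())
        leaf_map = {}
        for ln in Path(_require_file(blk["map"], "reconcile")).read_text(
                ).splitlines():
            if ln.strip():
                g, s = ln.split("\t")[:2]
                leaf_map[g.strip()] = s.strip()
        costs = reconcile.EventCosts(*blk.get("costs", [1.5, 3.0, 1.0]))
        cmp = reconcile.compare_models(gt, st, leaf_map, costs)
        report["stages"]["reconcile"] = {
            "params": {k: v for k, v in blk.items()},
            "verdict": cmp["verdict"],
            "dl": {"score": cmp["dl"].score, "dups": cmp["dl"].n_dup,
                   "losses": cmp["dl"].n_loss},
            "dtl": {"score": cmp["dtl"].score, "dups": cmp["dtl"].n_dup,
                    "transfers": cmp["dtl"].n_transfer,
                    "losses": cmp["dtl"].n_loss},
        }

    if "rates" in config:
        blk = config["rates"]
        loci = {name: seqio.read_alignment(_require_file(p, "rates"))
                for name, p in blk["loci"].items()}
        table = rates.genus_distance_ratios(
            loci, blk["genus_map"], blk.get("reference", "rpb2"))
        report["stages"]["rates"] = {
            "params": {"reference": table["reference"]},
            "ratios": {locus: {f"{a}-{b}": v for (a, b), v in entry.items()}
                       for locus, entry in table["ratios"].items()},
            "warnings": table["warnings"],
        }

    report["finished"] = time.time()
    outdir = config.get("outdir")
    if outdir:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        (Path(outdir) / "report.json").write_text(
            json.dumps(report, indent=2, default=str))
    return report
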