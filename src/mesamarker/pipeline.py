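"""Full-analysis orchestration: scan -> classify -> phylo -> promoters ->
expression -> report.

Stages communicate only through files in the run directory, so any stage can
be inspected or re-run in isolation, and a fixed config + seed yields
byte-identical outputs.  The manifest is written last and lists every stage
output with a checksum.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .core_io import (
    Alignment,
    DEFAULT_SPECIES_GROUPS,
    default_motifs_path,
    load_table2_matrix,
    read_allele_matrix,
    write_allele_matrix,
    write_fasta,
    write_tsv,
)
from .expression import relative_expression
from .phylo import bootstrap_support, is_group_monophyletic
from .promoter_scan import frequency_table, load_motifs, scan
from .synthetic_data import (
    ExpressionTruth,
    GeneFamilyTruth,
    gen_ct_table,
    gen_gene_family,
    gen_promoters,
)
from .tree import write_newick
from .variant_scan import (
    alignment_to_matrix,
    classify_individual,
    find_diagnostic_snps,
    heterozygosity_profile,
)

PROFILES = ("table2", "synthetic-full")

#: Standing analysis notes carried into every run report.
STANDING_WARNINGS = [
    "Phylogeny is computed with p-distance + neighbor joining (distance-based), "
    "not maximum likelihood; the group-separation result is topology-level.",
    "Recomputing the heterozygosity profile of the packaged validation matrix "
    "for the high group excluding B. medwediewii yields heterozygous calls at "
    "3 of the 6 marker positions (160, 189, 304), not 4 as sometimes stated.",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_config(profile: str = "table2") -> dict:
    return {
        "profile": profile,
        "seed": 0,
        "target_group": "high",
        "theta": 0.9,
        "require_contrast_fixed": True,
        "bootstrap_reps": 100,
        "matrix_path": None,     # default: the packaged validation matrix
        "motifs_path": None,     # default: the packaged motif dictionary
        "stages": None,          # default: all stages of the profile
    }


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(raw)
    return cfg


def _marker_rows(markers):
    return [
        {
            "position": m.position,
            "allele": m.diagnostic_allele,
            "penetrance": f"{m.penetrance:.6g}",
            "n_target": m.n_target,
            "n_contrast": m.n_contrast,
            "contrast_allele": m.contrast_fixed_allele or "none",
        }
        for m in markers
    ]


MARKER_COLUMNS = ["position", "allele", "penetrance", "n_target", "n_contrast", "contrast_allele"]


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the configured stages and return the manifest (also written).

    Raises ``StageError`` naming the failing stage; outputs of completed
    stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = config.get("profile", "table2")
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    all_stages = (
        ["scan", "heterozygosity", "classify"]
        if profile == "table2"
        else ["simulate", "scan", "heterozygosity", "classify", "phylo",
              "promoters", "expression"]
    )
    stages = config.get("stages") or all_stages
    stages = [s for s in all_stages if s in stages]
    if not stages:
        raise ValueError("no pipeline stages enabled")

    seed = int(config.get("seed", 0))
    theta = float(config.get("theta", 0.9))
    target_group = config.get("target_group", "high")
    outputs: dict[str, str] = {}
    summary: dict[str, object] = {}

    def emit(name: str, path: Path):
        outputs[name] = path.name

    # ---- inputs -------------------------------------------------------
    stage = "inputs"
    try:
        family = None
        if profile == "synthetic-full":
            truth = GeneFamilyTruth(seed=seed)
            family = gen_gene_family(truth)
            fasta = out / "family.fna"
            write_fasta(family, fasta)
            emit("family_fasta", fasta)
            matrix = alignment_to_matrix(Alignment(family))
            truth_json = out / "family_truth.json"
            truth_json.write_text(json.dumps({
                "planted_positions": truth.planted_positions,
                "planted_penetrance": truth.planted_penetrance,
                "het_rate_high": truth.het_rate_high,
                "het_rate_low": truth.het_rate_low,
                "background_mutation_rate": truth.background_mutation_rate,
                "cds_length": truth.cds_length,
                "n_high": truth.n_high,
                "n_low": truth.n_low,
                "seed": truth.seed,
            }, indent=2, sort_keys=True) + "\n")
            emit("family_truth", truth_json)
        elif config.get("matrix_path"):
            matrix = read_allele_matrix(config["matrix_path"])
        else:
            matrix = load_table2_matrix()
        matrix_path = out / "allele_matrix.tsv"
        write_allele_matrix(matrix, matrix_path)
        emit("allele_matrix", matrix_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    markers = []
    for stage in stages:
        try:
            if stage == "simulate":
                continue  # handled with inputs
            if stage == "scan":
                markers = find_diagnostic_snps(
                    matrix, target_group=target_group, theta=theta,
                    require_contrast_fixed=bool(config.get("require_contrast_fixed", True)),
                )
                path = out / "markers.tsv"
                write_tsv(_marker_rows(markers), path, MARKER_COLUMNS)
                emit("markers", path)
                summary["n_markers"] = len(markers)
                summary["marker_positions"] = [m.position for m in markers]
            elif stage == "heterozygosity":
                rows = []
                for grp in sorted(matrix.groups() - {"unassigned"}):
                    prof = heterozygosity_profile(matrix, group=grp)
                    rows.append({"subset": f"group:{grp}", "total": prof["total"],
                                 "het_positions": ",".join(map(str, sorted(prof["het_positions"]))) or "none"})
                for sp in sorted({ind.species_code for ind in matrix.individuals}):
                    prof = heterozygosity_profile(matrix, species=sp)
                    rows.append({"subset": f"species:{sp}", "total": prof["total"],
                                 "het_positions": ",".join(map(str, sorted(prof["het_positions"]))) or "none"})
                path = out / "heterozygosity.tsv"
                write_tsv(rows, path, ["subset", "total", "het_positions"])
                emit("heterozygosity", path)
            elif stage == "classify":
                if not markers:
                    raise ValueError("classification needs the scan stage")
                rows = []
                for ind in matrix.individuals:
                    res = classify_individual(markers, matrix.column_calls(ind.id),
                                              individual_id=ind.id)
                    rows.append({"individual": ind.id, "group": ind.group,
                                 "votes": res.votes_for_target, "covered": res.covered,
                                 "verdict": res.verdict})
                path = out / "classifications.tsv"
                write_tsv(rows, path, ["individual", "group", "votes", "covered", "verdict"])
                emit("classifications", path)
                expected = {"high": "target", "low": "contrast"}
                agree = sum(expected.get(r["group"]) == r["verdict"] for r in rows)
                summary["classification_agreement"] = f"{agree}/{len(rows)}"
            elif stage == "phylo":
                aln = Alignment(family)
                # strict comparison: heterozygous consensus codes count as
                # differing from homozygotes, keeping the group signal that
                # overlap matching would erase.
                tree = bootstrap_support(aln, n_reps=int(config.get("bootstrap_reps", 100)),
                                         seed=seed, strict=True)
                path = out / "tree.nwk"
                path.write_text(write_newick(tree) + "\n")
                emit("tree", path)
                high = [r.id for r in family if r.group == "high"]
                mono, bp = is_group_monophyletic(tree, high)
                summary["high_group_monophyletic"] = mono
                if mono and bp is not None:
                    support = None
                    all_leaves = frozenset(tree.leaf_names())
                    for node in tree.iter_nodes():
                        if node is tree.root or node.is_leaf:
                            continue
                        side = frozenset(node.leaf_names())
                        if frozenset({side, all_leaves - side}) == bp:
                            support = node.support
                    summary["group_bipartition_support"] = support
            elif stage == "promoters":
                motifs = load_motifs(config.get("motifs_path") or default_motifs_path())
                species = sorted(DEFAULT_SPECIES_GROUPS)
                planted = {sp: {"TATA-box": 1, "CAAT-box": 1, "ABRE": 1} for sp in species}
                planted["len"]["TATA-box"] = 2  # the 2-vs-1 TATA-box contrast
                promoters, motif_truth = gen_promoters(planted, motifs, seed=seed)
                table = frequency_table(promoters, motifs, DEFAULT_SPECIES_GROUPS)
                path = out / "motif_frequencies.tsv"
                table.counts.to_csv(path, sep="\t")
                emit("motif_frequencies", path)
                gpath = out / "motif_group_totals.tsv"
                table.group_totals.to_csv(gpath, sep="\t")
                emit("motif_group_totals", gpath)
                tpath = out / "promoter_truth.tsv"
                write_tsv([t.__dict__ for t in motif_truth], tpath,
                          ["species", "motif_name", "position", "strand"])
                emit("promoter_truth", tpath)
                hits_by_species = {
                    sp: {(h.motif_name, h.position, h.strand)
                         for h in scan(promoters[sp], motifs)}
                    for sp in promoters
                }
                recovered = sum(
                    (t.motif_name, t.position, t.strand) in hits_by_species[t.species]
                    for t in motif_truth
                )
                summary["planted_motifs_recovered"] = f"{recovered}/{len(motif_truth)}"
            elif stage == "expression":
                etruth = ExpressionTruth(seed=seed)
                ct = gen_ct_table(etruth)
                ct_path = out / "ct_table.tsv"
                ct.to_csv(ct_path, sep="\t", index=False)
                emit("ct_table", ct_path)
                rel = relative_expression(ct, "SAMT", etruth.reference_genes)
                rel_path = out / "relative_expression.tsv"
                rel.round(6).to_csv(rel_path, sep="\t", index=False)
                emit("relative_expression", rel_path)
                bark = rel[rel.tissue == "bark"].set_index("species")["rel_expr"]
                summary["high_bark_exceeds_low_bark"] = bool(
                    min(bark.get("ale", 0), bark.get("len", 0))
                    > max(bark.get("pen", float("inf")), bark.get("uti", float("inf")))
                    if {"ale", "len", "pen", "uti"} <= set(bark.index) else False
                )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    manifest = {
        "config": {k: v for k, v in sorted(config.items())},
        "seed": seed,
        "version": __version__,
        "stages_run": stages,
        "outputs": outputs,
        "checksums": {name: _sha256(out / fname) for name, fname in sorted(outputs.items())},
        "summary": summary,
        "warnings": list(STANDING_WARNINGS),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
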