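"""End-to-end orchestration: redundancy filter → UPGMA tree + bootstrap +
clade test → dual-alignment SDP consensus → repeat-motif discovery +
uniqueness test → consolidated report.

A run is driven by a single :class:`PipelineConfig` (YAML on disk), either
pointing at input files or asking for the bundled synthetic fixture
parameters.  One global seed is fanned out deterministically to the
stage-level seeds, so identical config + seed gives byte-identical
machine-readable outputs.  Every threshold actually used is echoed into the
run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import motif as motif_mod
from . import phylo, redundancy, sdp, seqio, synth

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    identity: float = 0.90
    bootstrap_reps: int = 1000
    sdp_z: float = 2.0
    motif_w_min: int = 5
    motif_w_max: int = 8
    motif_min_fraction: float = 0.6
    max_spacer: int = 40
    alpha: float = 0.05


@dataclass
class SyntheticParams:
    n_per_group: int = 20
    n_cols: int = 200
    n_sdp: int = 8
    n_conserved: int = 30
    leak: float = 0.05
    indel_rate: float = 0.02
    within_rate: float = 0.15
    between_rate: float = 0.08
    n_intergenic: int = 20
    intergenic_bp: int = 100
    core_word: str = "GGCCA"
    spacer: int = 12
    include_direct_repeat: bool = False
    n_background: int = 50


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    target_group: str = "YczR"
    mode: str = "files"                      # files | synthetic
    alignment_a: Optional[str] = None
    alignment_b: Optional[str] = None
    groups: Optional[str] = None
    intergenic: Optional[str] = None
    background: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    synthetic: SyntheticParams = field(default_factory=SyntheticParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**raw.pop("thresholds", {}))
        syn = SyntheticParams(**raw.pop("synthetic", {}))
        cfg = cls(**raw, thresholds=thr, synthetic=syn)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("files", "synthetic"):
            raise ValueError(f"mode must be files|synthetic, got {self.mode!r}")
        if self.mode == "files":
            for name in ("alignment_a", "alignment_b", "groups",
                         "intergenic", "background"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"files mode needs input {name!r}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
        if not 0 < self.thresholds.identity <= 1:
            raise ValueError("identity threshold must be in (0, 1]")
        if self.thresholds.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


@dataclass
class RunReport:
    config: dict
    n_input: int = 0
    n_representatives: int = 0
    clade_found: bool = False
    clade_support: Optional[float] = None
    clade_jaccard: Optional[float] = None
    consensus_columns: list[int] = field(default_factory=list)
    consensus_reference_residues: list[Optional[int]] = field(default_factory=list)
    s3det_clusters: Optional[dict] = None
    top_motif_consensus: Optional[str] = None
    top_motif_architecture: Optional[dict] = None
    uniqueness_regulon_fraction: Optional[float] = None
    uniqueness_background_fraction: Optional[float] = None
    files: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


def _load_inputs(cfg: PipelineConfig, seed: int):
    if cfg.mode == "files":
        aln_a = seqio.read_alignment(cfg.alignment_a, "protein")
        aln_b = seqio.read_alignment(cfg.alignment_b, "protein")
        groups = seqio.read_groups(cfg.groups)
        intergenic = seqio.read_fasta(cfg.intergenic, "dna")
        background = seqio.read_fasta(cfg.background, "dna")
        return aln_a, aln_b, groups, intergenic, background
    s = cfg.synthetic
    aln_a, groups, _, aln_b = synth.simulate_clustered_family(
        n_per_group=s.n_per_group, n_cols=s.n_cols, n_sdp=s.n_sdp,
        n_conserved=s.n_conserved, leak=s.leak, indel_rate=s.indel_rate,
        within_rate=s.within_rate, between_rate=s.between_rate, seed=seed,
        group_names=(cfg.target_group, "MocR"))
    intergenic, _ = synth.simulate_intergenic(
        n_seqs=s.n_intergenic, length_bp=s.intergenic_bp,
        core_word=s.core_word, spacer=s.spacer,
        include_direct_repeat=s.include_direct_repeat, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    background = [
        seqio.SequenceRecord(
            id=f"bg_{i:03d}",
            residues="".join("ACGT"[j] for j in
                             rng.integers(0, 4, size=s.intergenic_bp)))
        for i in range(s.n_background)]
    return aln_a, aln_b, groups, intergenic, background


def _write_distance_tsv(dm: phylo.DistanceMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, name in enumerate(dm.ids):
            fh.write(name + "\t" +
                     "\t".join(format(x, "g") for x in dm.d[i]) + "\n")


def _write_bootstrap_tsv(tree: phylo.Tree, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf_set\tsupport\n")
        for node in tree.internal_nodes():
            leaves = ",".join(sorted(node.leaf_set()))
            fh.write(f"{leaves}\t{node.support:.4f}\n")


def _write_logo_tsv(data: sdp.LogoData, path: Path) -> None:
    df = data.frequencies.copy()
    df.insert(0, "column", df.index)
    df.insert(1, "information_bits", np.round(data.information, 6))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _site_pwm(top: motif_mod.DiscoveredMotif,
              intergenic: list[seqio.SequenceRecord]) -> Optional[motif_mod.PWM]:
    """PWM over the full word–spacer–word span of the modal inverted pairs,
    the score matrix the uniqueness scan uses."""
    arch = top.architecture
    mode = arch.spacer_mode("inverted")
    if mode is None:
        return None
    texts = {r.id: r.residues.upper() for r in intergenic}
    spans = []
    for p in arch.pairs:
        if p.kind != "inverted" or p.spacer != mode:
            continue
        start = p.first[0]
        end = p.second[0] + arch.width
        span = texts[p.seq_id][start:end]
        if p.first[1] == "rc":       # normalise so the word comes first
            span = motif_mod.reverse_complement(span)
        spans.append(span)
    if not spans:
        return None
    return motif_mod.build_pwm(spans)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    thr = cfg.thresholds
    report = RunReport(config=cfg.to_dict())
    files = report.files

    logger.info("stage 1/5: loading inputs (mode=%s)", cfg.mode)
    aln_a, aln_b, groups, intergenic, background = _load_inputs(cfg, seeds[0])
    groups.check_covers(aln_a.ids)
    if set(aln_a.ids) != set(aln_b.ids):
        raise ValueError("alignments A and B contain different sequence ids")
    report.n_input = aln_a.n_rows

    logger.info("stage 2/5: redundancy filter at %.0f%% identity",
                100 * thr.identity)
    cs = redundancy.greedy_cluster(aln_a.rows, thr.identity)
    reps = cs.representatives
    report.n_representatives = len(reps)
    redundancy.write_cluster_report(cs, aln_a.rows, outdir / "clusters.tsv")
    files["clusters"] = str(outdir / "clusters.tsv")
    aln_a = aln_a.subset(reps)
    aln_b = aln_b.subset(reps)
    seqio.write_fasta(
        [seqio.SequenceRecord(id=r.id, residues=r.ungapped())
         for r in aln_a.rows], outdir / "representatives.fasta")
    files["representatives"] = str(outdir / "representatives.fasta")

    logger.info("stage 3/5: UPGMA + %d bootstrap replicates",
                thr.bootstrap_reps)
    dm = phylo.count_differences(aln_a)
    _write_distance_tsv(dm, outdir / "distances.tsv")
    files["distances"] = str(outdir / "distances.tsv")
    tree = phylo.bootstrap_support(aln_a, thr.bootstrap_reps, seeds[1])
    seqio.write_newick(tree, outdir / "tree.nwk")
    files["tree"] = str(outdir / "tree.nwk")
    _write_bootstrap_tsv(tree, outdir / "bootstrap.tsv")
    files["bootstrap"] = str(outdir / "bootstrap.tsv")
    target_ids = groups.members(cfg.target_group) & set(aln_a.ids)
    if not target_ids:
        raise ValueError(f"no sequences labelled {cfg.target_group!r} survive "
                         "the redundancy filter")
    clade = phylo.is_clade(tree, target_ids)
    report.clade_found = clade.found
    report.clade_jaccard = round(clade.jaccard, 4)
    report.clade_support = (None if clade.node.support is None
                            else round(clade.node.support, 4))

    logger.info("stage 4/5: SDP scoring (z >= %.2f) and consensus", thr.sdp_z)
    ref_id = aln_a.ids[0]
    sdp_report = sdp.build_report(aln_a, aln_b, groups, ref_id,
                                  z_threshold=thr.sdp_z,
                                  kmeans_seed=seeds[2])
    df = sdp_report.to_dataframe()
    ref_res = []
    for c in sorted(sdp_report.consensus):
        r = sdp.column_to_residue(aln_a, ref_id, c)
        ref_res.append(None if r is None else r + 1)   # 1-based in reports
    def _ref1(c: int):
        r = sdp.column_to_residue(aln_a, ref_id, int(c))
        return "" if r is None else r + 1

    df["ref_residue_1based"] = [_ref1(c) for c in df["column_A"]]
    df.to_csv(outdir / "sdp_report.tsv", sep="\t", index=False,
              float_format="%.6f")
    files["sdp_report"] = str(outdir / "sdp_report.tsv")
    report.consensus_columns = sorted(sdp_report.consensus)
    report.consensus_reference_residues = ref_res
    report.s3det_clusters = {
        str(k): int(v) for k, v in sorted(sdp_report.cluster_assignment.items())}
    for g in sorted(groups.groups):
        ids = groups.members(g) & set(aln_a.ids)
        if len(ids) >= 2:
            logo = sdp.logo_data(aln_a.subset(ids))
            _write_logo_tsv(logo, outdir / f"logo_{g}.tsv")
            files[f"logo_{g}"] = str(outdir / f"logo_{g}.tsv")

    logger.info("stage 5/5: motif discovery and uniqueness test")
    motifs = motif_mod.find_repeat_motifs(
        intergenic, w_min=thr.motif_w_min, w_max=thr.motif_w_max,
        min_fraction=thr.motif_min_fraction, max_spacer=thr.max_spacer)
    with open(outdir / "motifs.tsv", "w") as fh:
        fh.write("rank\tconsensus\trefined\twidth\tcoverage\tn_occurrences\t"
                 "n_inverted\tn_direct\tmodal_spacer_inverted\tspacer_sd\n")
        for rank, m in enumerate(motifs, start=1):
            a = m.architecture
            fh.write(f"{rank}\t{m.consensus}\t{m.refined_consensus}\t"
                     f"{a.width}\t{a.coverage:.3f}\t{a.n_occurrences}\t"
                     f"{a.n_inverted}\t{a.n_direct}\t"
                     f"{a.spacer_mode('inverted')}\t{a.spacer_sd():.3f}\n")
    files["motifs"] = str(outdir / "motifs.tsv")
    if motifs:
        top = motifs[0]
        report.top_motif_consensus = top.consensus
        arch = top.architecture
        report.top_motif_architecture = {
            "width": arch.width, "coverage": round(arch.coverage, 3),
            "n_inverted": arch.n_inverted, "n_direct": arch.n_direct,
            "modal_spacer_inverted": arch.spacer_mode("inverted"),
            "modal_spacer_direct": arch.spacer_mode("direct"),
        }
        motif_mod.write_meme([("motif_1", top.pwm)], outdir / "motif.meme")
        files["meme"] = str(outdir / "motif.meme")
        occ = motif_mod.scan(top.pwm, intergenic, both_strands=True,
                             p_threshold=1e-3)
        motif_mod.write_occurrences_bed(occ, outdir / "occurrences.tsv")
        files["occurrences"] = str(outdir / "occurrences.tsv")
        site = _site_pwm(top, intergenic)
        if site is not None:
            uniq = motif_mod.uniqueness_test(site, intergenic, background,
                                             alpha=thr.alpha)
            report.uniqueness_regulon_fraction = round(
                uniq.regulon_fraction, 4)
            report.uniqueness_background_fraction = round(
                uniq.background_fraction, 4)
            with open(outdir / "uniqueness.tsv", "w") as fh:
                fh.write("set\tseqid\tbest_p\tadjusted_p\tn_tests\tsignificant\n")
                for name, verdicts in (("regulon", uniq.regulon),
                                       ("background", uniq.background)):
                    for v in verdicts:
                        fh.write(f"{name}\t{v.seq_id}\t{v.best_p:.3e}\t"
                                 f"{v.adjusted_p:.3e}\t{v.n_tests}\t"
                                 f"{int(v.significant)}\n")
            files["uniqueness"] = str(outdir / "uniqueness.tsv")

    files["run_report"] = str(outdir / "run_report.json")
    (outdir / "run_report.json").write_text(report.to_json() + "\n")
    return report


def generate_fixture(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete synthetic input bundle plus a ready-to-run config.

    The family uses the clustered background (so the tree stage has signal)
    with the default planted-SDP budget; the intergenic set carries the
    GGCCA / 12-bp-spacer inverted-repeat architecture.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    syn = SyntheticParams()
    aln_a, groups, family_truth, aln_b = synth.simulate_clustered_family(
        n_per_group=syn.n_per_group, n_cols=syn.n_cols, n_sdp=syn.n_sdp,
        n_conserved=syn.n_conserved, leak=syn.leak,
        indel_rate=syn.indel_rate, within_rate=syn.within_rate,
        between_rate=syn.between_rate, seed=seed)
    intergenic, motif_truth = synth.simulate_intergenic(
        n_seqs=syn.n_intergenic, length_bp=syn.intergenic_bp,
        core_word=syn.core_word, spacer=syn.spacer, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    background = [
        seqio.SequenceRecord(
            id=f"bg_{i:03d}",
            residues="".join("ACGT"[j] for j in
                             rng.integers(0, 4, size=syn.intergenic_bp)))
        for i in range(syn.n_background)]

    paths = {
        "alignment_a": out / "alignment_a.fasta",
        "alignment_b": out / "alignment_b.fasta",
        "groups": out / "groups.tsv",
        "intergenic": out / "intergenic.fasta",
        "background": out / "background.fasta",
        "family_truth": out / "family_truth.tsv",
        "motif_truth": out / "motif_truth.tsv",
        "config": out / "config.yaml",
    }
    seqio.write_fasta(aln_a.rows, paths["alignment_a"])
    seqio.write_fasta(aln_b.rows, paths["alignment_b"])
    seqio.write_groups(groups, paths["groups"])
    seqio.write_fasta(intergenic, paths["intergenic"])
    seqio.write_fasta(background, paths["background"])
    synth.write_family_truth(family_truth, paths["family_truth"])
    synth.write_motif_truth(motif_truth, paths["motif_truth"])

    config = {
        "mode": "files",
        "outdir": str(out / "results"),
        "seed": seed,
        "target_group": "YczR",
        "alignment_a": str(paths["alignment_a"]),
        "alignment_b": str(paths["alignment_b"]),
        "groups": str(paths["groups"]),
        "intergenic": str(paths["intergenic"]),
        "background": str(paths["background"]),
        "thresholds": {"bootstrap_reps": 200},
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths
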