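"""Staged pipeline orchestration over a workspace directory.

Each stage reads the previous stage's files, writes its own outputs and
a manifest (parameters, seed, SHA-256 of inputs and outputs) so any
stage can be reproduced and verified bit-for-bit.  The stage graph:

    simulate → trim → collapse → consensus → map → genotype
                                   └→ popgen / express / enrich
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import consensus as cns
from . import exprstats as ex
from . import genotyping as gt
from . import popgen as pg
from .seqio import SeqRecord, read_fasta, read_fastq, write_fasta, write_fastq
from .simulate import (
    GENOTYPES,
    SimulationConfig,
    emit_annotations,
    emit_contigs,
    read_go_map,
    simulate_reads,
    simulate_transcriptome,
    write_contigs,
    write_go_map,
    write_reads,
)
from .trim import TrimPolicy, trim_pairs

STAGES = (
    "simulate",
    "trim",
    "collapse",
    "consensus",
    "map",
    "genotype",
    "popgen",
    "express",
    "enrich",
)
_PRODUCER = {
    "trim": "simulate",
    "collapse": "simulate",
    "consensus": "collapse",
    "map": "consensus",
    "genotype": "map",
    "popgen": "genotype",
    "express": "map",
    "enrich": "express",
}

SELFER_LABELS = ["selfer1", "selfer2", "outgroup"]
INGROUP_SELFERS = ["selfer1", "selfer2"]


class StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """File-based pipeline over one workspace directory."""

    def __init__(self, workdir: str | Path, config: SimulationConfig | None = None):
        self.workdir = Path(workdir)
        self.config = config or SimulationConfig()
        self.workdir.mkdir(parents=True, exist_ok=True)

    # -- helpers -----------------------------------------------------------

    def stage_dir(self, stage: str) -> Path:
        d = self.workdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _require(self, stage: str, *paths: Path) -> None:
        for p in paths:
            if not p.exists():
                raise StageError(
                    f"missing input {p.name}: run the '{_PRODUCER[stage]}' stage first"
                )

    def _manifest(self, stage: str, inputs: list[Path], outputs: list[Path], params: dict) -> None:
        man = {
            "stage": stage,
            "seed": self.config.seed,
            "params": params,
            "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
        }
        with open(self.stage_dir(stage) / "manifest.json", "w") as fh:
            json.dump(man, fh, indent=1, sort_keys=True)

    # -- stages ------------------------------------------------------------

    def run_simulate(self) -> None:
        d = self.stage_dir("simulate")
        truth = simulate_transcriptome(self.config)
        reads = simulate_reads(truth, self.config)
        contigs = emit_contigs(truth, self.config)
        guides, go_map = emit_annotations(truth)
        truth.write(d)
        write_reads(reads, d)
        write_contigs(contigs, d)
        write_fasta(guides, d / "guides.fasta")
        write_go_map(go_map, d / "go_map.tsv")
        outputs = sorted(d.glob("*.fasta")) + sorted(d.glob("*.fastq")) + sorted(d.glob("*.tsv"))
        self._manifest("simulate", [], outputs, asdict(self.config))

    def run_trim(self, policy: TrimPolicy = TrimPolicy()) -> None:
        sim, d = self.stage_dir("simulate"), self.stage_dir("trim")
        outputs = []
        inputs = []
        for g in GENOTYPES:
            f1, f2 = sim / f"{g}_1.fastq", sim / f"{g}_2.fastq"
            self._require("trim", f1, f2)
            inputs += [f1, f2]
            pairs = list(zip(read_fastq(f1), read_fastq(f2)))
            kept = trim_pairs(pairs, policy)
            o1, o2 = d / f"{g}_1.fastq", d / f"{g}_2.fastq"
            write_fastq([a for a, _ in kept], o1)
            write_fastq([b for _, b in kept if b is not None], o2)
            outputs += [o1, o2]
        self._manifest("trim", inputs, outputs, asdict(policy))

    def run_collapse(self, min_contig_len: int = 100) -> None:
        sim, d = self.stage_dir("simulate"), self.stage_dir("collapse")
        inputs, outputs = [], []
        for g in GENOTYPES:
            f = sim / f"{g}_contigs.fasta"
            self._require("collapse", f)
            inputs.append(f)
            collapsed = cns.collapse_redundant(read_fasta(f), min_contig_len)
            out = d / f"{g}_contigs.fasta"
            write_fasta(collapsed, out)
            outputs.append(out)
        self._manifest("collapse", inputs, outputs, {"min_contig_len": min_contig_len})

    def run_consensus(
        self,
        criteria: cns.GroupingCriteria = cns.GroupingCriteria(),
        min_samples: int = 2,
        singleton_min_len: int = 1000,
    ) -> None:
        col, sim, d = self.stage_dir("collapse"), self.stage_dir("simulate"), self.stage_dir("consensus")
        samples = {}
        inputs = []
        for g in GENOTYPES:
            f = col / f"{g}_contigs.fasta"
            self._require("consensus", f)
            inputs.append(f)
            samples[g] = read_fasta(f)
        guides_path = sim / "guides.fasta"
        self._require("consensus", guides_path)
        guides = read_fasta(guides_path)

        pooled = [c for recs in samples.values() for c in recs]
        stages_stats = [("pooled_input", cns.transcriptome_stats(pooled))]
        groups, leftovers = cns.build_groups(samples, criteria, min_samples)
        consensi = []
        group_rows = []
        for grp in groups:
            try:
                consensi.append(cns.consense(grp))
            except cns.GroupAlignmentError:
                leftovers.extend(grp.members.values())
                continue
            for s, rec in sorted(grp.members.items()):
                group_rows.append((grp.group_id, s, rec.id, grp.strands.get(rec.id, "+")))
        stages_stats.append(("rbh_consensus", cns.transcriptome_stats(consensi)))
        consensi, leftovers, ext_log = cns.incorporate_extensions(consensi, leftovers)
        stages_stats.append(("extended", cns.transcriptome_stats(consensi)))
        consensi, join_log = cns.join_fragments(consensi, guides)
        stages_stats.append(("fragments_joined", cns.transcriptome_stats(consensi)))
        consensi = cns.add_singletons(consensi, leftovers, guides, singleton_min_len)
        stages_stats.append(("final", cns.transcriptome_stats(consensi)))

        out_fa = d / "consensus.fasta"
        write_fasta(consensi, out_fa)
        # functional annotation of the final set: best guide per consensus
        guide_index = cns.build_guide_index(guides)
        annot_tsv = d / "annotation.tsv"
        with open(annot_tsv, "w") as fh:
            fh.write("consensus_id\tguide_id\tidentity\tn_aligned\n")
            for rec in consensi:
                gh = cns.best_guide_hit(rec, guides, guide_index)
                if gh is not None:
                    fh.write(f"{rec.id}\t{gh.guide_id}\t{gh.identity:.3f}\t{gh.n_aligned}\n")
        groups_tsv = d / "groups.tsv"
        with open(groups_tsv, "w") as fh:
            fh.write("group_id\tsample\tcontig_id\tstrand\n")
            for row in group_rows:
                fh.write("\t".join(row) + "\n")
        stats_tsv = d / "stats.tsv"
        with open(stats_tsv, "w") as fh:
            fh.write("stage\tn50\tmean\ttotal\tcount\n")
            for name, st in stages_stats:
                fh.write(f"{name}\t{st.n50}\t{st.mean_length:.1f}\t{st.total_length}\t{st.n_contigs}\n")
        log_json = d / "log.json"
        with open(log_json, "w") as fh:
            json.dump(
                {
                    "extensions_merged": ext_log.merged,
                    "extensions_ambiguous": ext_log.ambiguous,
                    "fragments_joined": join_log.joined,
                    "fragments_conflicting": join_log.conflicting,
                },
                fh,
                indent=1,
            )
        self._manifest(
            "consensus",
            inputs + [guides_path],
            [out_fa, annot_tsv, groups_tsv, stats_tsv, log_json],
            {"criteria": asdict(criteria), "min_samples": min_samples},
        )

    def run_map(self, max_mismatch_frac: float = 0.05) -> None:
        trim_d, con_d, d = self.stage_dir("trim"), self.stage_dir("consensus"), self.stage_dir("map")
        ref_path = con_d / "consensus.fasta"
        self._require("map", ref_path)
        reference = read_fasta(ref_path)
        index = gt.ReferenceIndex(reference)
        inputs, outputs = [ref_path], []
        for g in GENOTYPES:
            f1, f2 = trim_d / f"{g}_1.fastq", trim_d / f"{g}_2.fastq"
            self._require("map", f1, f2)
            inputs += [f1, f2]
            reads = read_fastq(f1) + read_fastq(f2)
            alns = gt.map_reads(reads, index, max_mismatch_frac)
            out = d / f"{g}.sam"
            write_sam(alns, reference, out)
            outputs.append(out)
        self._manifest("map", inputs, outputs, {"max_mismatch_frac": max_mismatch_frac})

    def run_genotype(self, het_prior: float = 0.001) -> None:
        con_d, map_d, d = self.stage_dir("consensus"), self.stage_dir("map"), self.stage_dir("genotype")
        ref_path = con_d / "consensus.fasta"
        self._require("genotype", ref_path)
        reference = read_fasta(ref_path)
        inputs, outputs = [ref_path], []
        all_genotypes: dict[str, dict[str, gt.LocusGenotype]] = {}
        for g in GENOTYPES:
            sam = map_d / f"{g}.sam"
            self._require("genotype", sam)
            inputs.append(sam)
            alns = gt.read_sam(sam)
            all_genotypes[g] = gt.genotype_sample(alns, reference, het_prior)
            out = d / f"{g}_called.fasta"
            write_fasta(
                [SeqRecord(lid, lg.sequence) for lid, lg in sorted(all_genotypes[g].items()) if lg.present],
                out,
            )
            outputs.append(out)
        flags = gt.flag_mapping_errors(all_genotypes, SELFER_LABELS)
        flags_tsv = d / "locus_flags.tsv"
        with open(flags_tsv, "w") as fh:
            fh.write("locus\tflag\n")
            for lid, fl in sorted(flags.items()):
                fh.write(f"{lid}\t{fl}\n")
        summary = d / "summary.tsv"
        with open(summary, "w") as fh:
            fh.write("sample\tn_loci\tmean_coverage\tsd_coverage\tn_het_loci\ttotal_bp\n")
            for g in GENOTYPES:
                present = [lg for lg in all_genotypes[g].values() if lg.present]
                covs = np.array([lg.mean_coverage for lg in present]) if present else np.zeros(1)
                n_het = sum(1 for lg in present if lg.het_site_count > 0)
                total = sum(len(lg.sequence) for lg in present)
                fh.write(
                    f"{g}\t{len(present)}\t{covs.mean():.1f}\t{covs.std():.1f}\t{n_het}\t{total}\n"
                )
        # per-locus het counts for popgen
        het_tsv = d / "locus_genotypes.tsv"
        with open(het_tsv, "w") as fh:
            fh.write("sample\tlocus\tpresent\tmean_coverage\thet_sites\n")
            for g in GENOTYPES:
                for lid, lg in sorted(all_genotypes[g].items()):
                    fh.write(
                        f"{g}\t{lid}\t{int(lg.present)}\t{lg.mean_coverage:.2f}\t{lg.het_site_count}\n"
                    )
        outputs += [flags_tsv, summary, het_tsv]
        self._manifest("genotype", inputs, outputs, {"het_prior": het_prior})
        self._genotypes_cache = all_genotypes

    def _load_genotypes(self) -> dict[str, dict[str, gt.LocusGenotype]]:
        if hasattr(self, "_genotypes_cache"):
            return self._genotypes_cache
        d = self.stage_dir("genotype")
        meta_path = d / "locus_genotypes.tsv"
        self._require("popgen", meta_path)
        meta: dict[tuple[str, str], tuple[bool, float, int]] = {}
        with open(meta_path) as fh:
            fh.readline()
            for line in fh:
                g, lid, present, cov, het = line.rstrip("\n").split("\t")
                meta[(g, lid)] = (present == "1", float(cov), int(het))
        out: dict[str, dict[str, gt.LocusGenotype]] = {}
        for g in GENOTYPES:
            called = {r.id: r.seq for r in read_fasta(d / f"{g}_called.fasta")}
            out[g] = {}
            for (gg, lid), (present, cov, het) in meta.items():
                if gg != g:
                    continue
                seq = called.get(lid, "")
                out[g][lid] = gt.LocusGenotype(lid, seq, cov, het, present)
        return out

    def run_popgen(self) -> None:
        d = self.stage_dir("popgen")
        genotypes = self._load_genotypes()
        flags_path = self.stage_dir("genotype") / "locus_flags.tsv"
        self._require("popgen", flags_path)
        suspect = set()
        with open(flags_path) as fh:
            fh.readline()
            for line in fh:
                lid, fl = line.rstrip("\n").split("\t")
                if fl == "SUSPECT":
                    suspect.add(lid)
        filtered = {
            g: {lid: lg for lid, lg in gset.items() if lid not in suspect and lg.sequence}
            for g, gset in genotypes.items()
        }
        # restrict to loci with sequences available in all samples
        shared = set.intersection(*(set(f) for f in filtered.values()))
        filtered = {g: {lid: f[lid] for lid in shared} for g, f in filtered.items()}
        cset = pg.conservative_set(filtered, SELFER_LABELS)
        matrix = pg.divergence_matrix(filtered, cset)
        samples = sorted(filtered)
        mat_tsv = d / "divergence_matrix.tsv"
        pg.write_divergence_matrix(matrix, samples, mat_tsv)
        ingroup = [filtered[g] for g in ("outcrosser", "selfer1", "selfer2")]
        theta_tsv = d / "theta_w.tsv"
        try:
            th = pg.watterson_theta(ingroup, cset)
            with open(theta_tsv, "w") as fh:
                fh.write("n\tS\ta_n\tL\ttheta_w\n")
                fh.write(f"{th.n}\t{th.segregating_sites}\t{th.a_n:.4f}\t{th.length}\t{th.theta_w:.6f}\n")
        except ValueError:
            theta_tsv.write_text("n\tS\ta_n\tL\ttheta_w\n")
        cset_tsv = d / "conservative_set.tsv"
        with open(cset_tsv, "w") as fh:
            fh.write("locus\n")
            for lid in cset.locus_ids:
                fh.write(lid + "\n")
        self._manifest("popgen", [flags_path], [mat_tsv, theta_tsv, cset_tsv], {})

    def run_express(self, reps: int = 10_000) -> None:
        con_d, map_d, d = self.stage_dir("consensus"), self.stage_dir("map"), self.stage_dir("express")
        ref_path = con_d / "consensus.fasta"
        self._require("express", ref_path)
        reference = read_fasta(ref_path)
        lengths = {r.id: len(r) for r in reference}
        inputs = [ref_path]
        tables: dict[str, dict[str, ex.ExpressionRecord]] = {}
        counts_by_sample: dict[str, dict[str, int]] = {}
        for g in GENOTYPES:
            sam = map_d / f"{g}.sam"
            self._require("express", sam)
            inputs.append(sam)
            alns = gt.read_sam(sam)
            counts, _ = ex.count_fragments(alns)
            counts_by_sample[g] = counts
            tables[g] = ex.expression_table(counts, lengths, g)
        mat = d / "expression_matrix.tsv"
        ex.write_expression_matrix(tables, mat)
        corr_tsv = d / "correlations.tsv"
        with open(corr_tsv, "w") as fh:
            fh.write("sample_a\tsample_b\tr\tci_low\tci_high\tn\n")
            names = list(GENOTYPES)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    fa = {k: v.fpkm for k, v in tables[a].items()}
                    fb = {k: v.fpkm for k, v in tables[b].items()}
                    res = ex.correlate_samples(fa, fb, a, b, reps=reps, seed=self.config.seed)
                    fh.write(
                        f"{a}\t{b}\t{res.r:.4f}\t{res.ci_low:.4f}\t{res.ci_high:.4f}\t{res.n_loci}\n"
                    )
        de_files = []
        for sel in SELFER_LABELS:
            res = ex.differential_expression(
                counts_by_sample["outcrosser"],
                counts_by_sample[sel],
                sum(counts_by_sample["outcrosser"].values()),
                sum(counts_by_sample[sel].values()),
                lengths,
            )
            f = d / f"de_outcrosser_vs_{sel}.tsv"
            with open(f, "w") as fh:
                fh.write("locus\tcount_outcrosser\tcount_selfer\tfold_change\tp\tq\tsignificant\tdirection\n")
                for r in res:
                    fold = "inf" if r.infinite_fold else f"{r.fold_change:.4f}"
                    fh.write(
                        f"{r.locus_id}\t{r.count_a}\t{r.count_b}\t{fold}\t{r.p:.3e}\t{r.q:.3e}\t"
                        f"{int(r.significant)}\t{r.direction}\n"
                    )
            de_files.append(f)
        self._manifest("express", inputs, [mat, corr_tsv] + de_files, {"reps": reps})

    def run_enrich(self, fdr: float = 0.05) -> None:
        sim, exp_d, d = self.stage_dir("simulate"), self.stage_dir("express"), self.stage_dir("enrich")
        con_d = self.stage_dir("consensus")
        go_path = sim / "go_map.tsv"
        annot_path = con_d / "annotation.tsv"
        self._require("enrich", go_path, annot_path)
        term_map = read_go_map(go_path)
        # consensus id -> annotated gene id via its best guide protein
        gene_of: dict[str, str] = {}
        with open(annot_path) as fh:
            fh.readline()
            for line in fh:
                cid, gid, *_ = line.rstrip("\n").split("\t")
                gene_of[cid] = gid.removeprefix("guide_")
        de_sets = []
        inputs = [go_path, annot_path]
        reference_loci: set[str] = set()
        for sel in INGROUP_SELFERS:
            f = exp_d / f"de_outcrosser_vs_{sel}.tsv"
            self._require("enrich", f)
            inputs.append(f)
            res = []
            with open(f) as fh:
                fh.readline()
                for line in fh:
                    cols = line.rstrip("\n").split("\t")
                    lid = cols[0]
                    reference_loci.add(lid)
                    fold = math_inf_safe(cols[3])
                    res.append(
                        ex.DEResult(
                            lid, int(cols[1]), int(cols[2]), fold, cols[3] == "inf",
                            float(cols[4]), float(cols[5]), cols[6] == "1",
                        )
                    )
            de_sets.append(res)
        outputs = []
        annotated = set(term_map)
        for direction in ("up", "down"):
            shared = ex.intersect_de_sets(de_sets, direction)
            test = {gene_of[c] for c in shared if c in gene_of} & annotated
            ref = {gene_of[c] for c in reference_loci if c in gene_of} & annotated
            out = d / f"enrichment_{direction}.tsv"
            with open(out, "w") as fh:
                fh.write("term\ttest_with\ttest_without\trest_with\trest_without\tp\tq\tdirection\tsignificant\n")
                if test:
                    for r in ex.go_enrichment(test, ref, term_map, fdr):
                        fh.write(
                            f"{r.term}\t{r.test_with}\t{r.test_without}\t{r.rest_with}\t"
                            f"{r.rest_without}\t{r.p:.3e}\t{r.q:.3e}\t{r.direction}\t{int(r.significant)}\n"
                        )
            outputs.append(out)
        self._manifest("enrich", inputs, outputs, {"fdr": fdr})

    def run_stage(self, name: str) -> None:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        getattr(self, f"run_{name}")()

    def run_all(self) -> None:
        for stage in STAGES:
            self.run_stage(stage)


def math_inf_safe(s: str) -> float:
    import math

    return math.inf if s == "inf" else float(s)


def write_sam(
    alignments: list,
    reference: list[SeqRecord],
    path: str | Path,
) -> None:
    """Minimal deterministic SAM writer for mapped ungapped reads."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for r in reference:
            fh.write(f"@SQ\tSN:{r.id}\tLN:{len(r)}\n")
        for a in alignments:
            if not a.mapped:
                continue
            flag = 16 if a.strand == "-" else 0
            qual = (
                "".join(chr(q + 33) for q in a.quals) if a.quals is not None else "*"
            )
            fh.write(
                f"{a.read_id}\t{flag}\t{a.locus_id}\t{a.position + 1}\t60\t"
                f"{len(a.seq)}M\t*\t0\t0\t{a.seq}\t{qual}\tNM:i:{a.mismatch_count}\n"
            )
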