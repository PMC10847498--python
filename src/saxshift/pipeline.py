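"""Orchestration of the full analysis with a declarative run config.

Stages run in a fixed order — filter, brlens (or geneshop), date,
classe-fit, classe-map, rates — each reading files produced by earlier
stages (or supplied by the user) and recording inputs, parameter values
and output hashes in a JSON run manifest, which is sufficient to
reproduce any stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import classe, congruence, dating, filters, rates, states, trees

log = logging.getLogger(__name__)

STAGE_ORDER = ("filter", "brlens", "geneshop", "date",
               "classe_fit", "classe_map", "rates")


class RunConfig:
    """Validated, serialisable pipeline configuration.

    Top-level keys: ``stages`` (list of stage names to run), ``seed``,
    ``outdir``, and one mapping per stage with its parameters and input
    paths.  Flags given on the command line override config values.
    """

    def __init__(self, data: dict) -> None:
        self.data = dict(data)
        self.stages = list(self.data.get("stages", []))
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        self.seed = int(self.data.get("seed", 0))
        self.outdir = Path(self.data.get("outdir", "saxshift_out"))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def stage_opts(self, stage: str) -> dict:
        return dict(self.data.get(stage, {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {},
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    ordered = [s for s in STAGE_ORDER if s in config.stages]
    artefacts: dict[str, Path] = {}
    for stage in ordered:
        opts = config.stage_opts(stage)
        entry = {"options": {k: v for k, v in opts.items()}, "inputs": {},
                 "outputs": {}}
        try:
            _run_stage(stage, opts, config, outdir, artefacts, entry)
        except Exception as exc:
            entry["error"] = str(exc)
            manifest["stages"][stage] = entry
            _write_manifest(manifest, outdir)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = entry
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _record(entry: dict, role: str, path: Path) -> None:
    entry["outputs" if role == "out" else "inputs"][str(path)] = _sha256(path)


def _run_stage(stage, opts, config, outdir, artefacts, entry):
    if stage == "filter":
        seqs = filters.SequenceSet.from_fasta(opts["fasta"])
        entry["inputs"][opts["fasta"]] = _sha256(Path(opts["fasta"]))
        seqs = filters.drop_short(seqs, int(opts.get("min_len", 300)))
        seqs = filters.drop_relative_short(seqs, float(opts.get("rel_frac", 0.4)))
        if seqs.is_aligned() and len(seqs):
            seqs = filters.strip_gappy_sites(
                seqs, float(opts.get("max_missing", 0.95)))
        out = outdir / "filtered.fasta"
        seqs.to_fasta(str(out))
        artefacts["filtered_fasta"] = out
        _record(entry, "out", out)

    elif stage in ("brlens", "geneshop"):
        sp = trees.read_newick(Path(opts["species_tree"]).read_text())
        gts = trees.read_newick_list(Path(opts["gene_trees"]).read_text())
        entry["inputs"][opts["species_tree"]] = _sha256(Path(opts["species_tree"]))
        entry["inputs"][opts["gene_trees"]] = _sha256(Path(opts["gene_trees"]))
        if stage == "brlens":
            dated_input, report = congruence.branchwise_lengths(sp, gts)
            out = outdir / "species_brlens.nwk"
            out.write_text(trees.write_newick(
                congruence.impute_missing_lengths(dated_input)) + "\n")
            rep = outdir / "coverage.tsv"
            with open(rep, "w") as fh:
                fh.write("branch\tn_matches\n")
                for bid, n in sorted(report.counts.items()):
                    fh.write(f"{bid}\t{n}\n")
            artefacts["brlens_tree"] = out
            _record(entry, "out", out)
            _record(entry, "out", rep)
        else:
            ranked = congruence.congruence_rank(gts, sp)
            locus_taxa = {f"locus_{i}": gt.taxa for i, gt in enumerate(gts)}
            chosen = congruence.gene_shop(ranked, locus_taxa,
                                          k=int(opts.get("k", 2)),
                                          taxa=set(sp.taxa))
            out = outdir / "geneshop.txt"
            out.write_text("\n".join(chosen) + "\n")
            _record(entry, "out", out)

    elif stage == "date":
        tree_path = opts.get("tree") or artefacts.get("brlens_tree")
        tr = trees.read_newick(Path(tree_path).read_text())
        cal = trees.read_calibrations(Path(opts["calibrations"]).read_text())
        cfg = dating.DatingConfig(
            kappa=float(opts.get("kappa", 1.0)),
            site_count=int(opts.get("sites", 100_000)),
            cv_grid=tuple(float(k) for k in opts.get(
                "cv_grid", dating.DEFAULT_CV_GRID)),
            root_age=opts.get("root_age"))
        if opts.get("cross_validate", False):
            kappa, table = dating.cross_validate(tr, cal, cfg)
            cfg.kappa = kappa
            entry["cv"] = table
        chron = dating.date_tree(tr, cal, cfg)
        out = outdir / "chronogram.nwk"
        out.write_text(trees.write_newick(chron.tree) + "\n")
        artefacts["chronogram"] = out
        entry["root_age_estimate"] = chron.tree.root_age()
        _record(entry, "out", out)

    elif stage == "classe_fit":
        tree_path = opts.get("tree") or artefacts.get("chronogram")
        tr = trees.read_newick(Path(tree_path).read_text(), units="myr")
        tr.set_ages_from_lengths()
        table = states.load_assignments(opts["assignments"])
        space = states.enumerate_states(
            max_range=int(opts.get("max_range", 2)))
        pruned, tip_states, dropped = states.match_tree_to_assignments(
            tr, table, space)
        samples = classe.mcmc_sample(
            pruned, tip_states, space,
            n_iter=int(opts.get("iters", 2000)),
            seed=config.seed,
            rho=float(opts.get("rho", classe.DEFAULT_RHO)))
        out = outdir / "posterior.tsv"
        samples.to_csv(out, sep="\t", index=False)
        artefacts["posterior"] = out
        artefacts["classe_inputs"] = (pruned, tip_states, space)
        entry["n_dropped_tips"] = len(dropped)
        _record(entry, "out", out)

    elif stage == "classe_map":
        pruned, tip_states, space = artefacts["classe_inputs"]
        import pandas as pd
        post = pd.read_csv(artefacts["posterior"], sep="\t")
        n_maps = int(opts.get("n_maps", 100))
        rng = np.random.default_rng(config.seed + 1)
        draws = post.sample(n=min(n_maps, len(post)), replace=n_maps > len(post),
                            random_state=int(rng.integers(2**31)))
        maps = []
        for _, row in draws.iterrows():
            p = classe.ClasseParams().with_rates(
                **{k: row[k] for k in classe.RATE_NAMES if k in row})
            gen = classe.build_generator(space, p)
            mapper = classe.StochasticMapper(
                pruned, tip_states, gen,
                rho=float(opts.get("rho", classe.DEFAULT_RHO)))
            maps.append(mapper.draw(rng))
        artefacts["maps"] = maps
        out = outdir / "map_events.tsv"
        with open(out, "w") as fh:
            fh.write("map\tage\tbranch\tkind\tdetail\n")
            for i, m in enumerate(maps):
                for e in m.events:
                    fh.write(f"{i}\t{e.age:.4f}\t{e.branch}\t{e.kind}\t"
                             f"{';'.join(map(str, e.detail))}\n")
        _record(entry, "out", out)

    elif stage == "rates":
        maps = artefacts["maps"]
        bounds = tuple(float(b) for b in opts.get("windows", (15, 10, 5)))
        windows = rates.TimeWindows(bounds)
        post = rates.rates_through_time(maps, windows)
        out = outdir / "rates.tsv"
        post.summary().to_csv(out, sep="\t", index=False)
        _record(entry, "out", out)

    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")
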