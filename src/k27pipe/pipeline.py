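"""End-to-end orchestration: simulate -> mark -> diff -> expr -> compare ->
profile -> enrich from a single config, with a manifest of outputs.

Every stage is also callable on its own through the module APIs; the
orchestrated run produces identical results because all randomness lives in
the simulation seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import comparative, differential, enrichment, expression, marking, profiles
from .io_formats import write_table
from .synthetic_data import SimulationConfig, simulate_all, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters at their study defaults plus a simulation block."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    flank_bp: int = 200
    min_peak_len: int = 200
    marking_rule: str = "overlap"
    log2_cut: float = 2.0
    q_cut: float = 0.05
    fdr: float = 0.01
    ses_bin_bp: int = 1000
    deg_epsilon: float = 0.01
    min_fpkm_for_reads: float = 0.01
    metagene_flank_bp: int = 1000
    nucleation_intron_bp: int = 500
    spreading_e_min: float = 2.0
    spreading_b_spread: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.pop("simulation", {})
        if isinstance(sim, dict):
            known_sim = set(SimulationConfig.__dataclass_fields__)
            unknown_sim = set(sim) - known_sim
            if unknown_sim:
                raise ValueError(f"unknown simulation keys: {sorted(unknown_sim)}")
            for key in ("gene_length_bp", "tissues", "vernalization_timepoints",
                        "lines", "study_tissues"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the whole pipeline on a simulated dataset; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    ds = simulate_all(sim)
    input_paths = write_dataset(ds, out / "inputs")
    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        p = out / name
        write_table(df, p, index=index)
        outputs[name] = p

    # --- marking ------------------------------------------------------------
    callsets = {
        s: marking.call_marked_genes(
            ds.peaks[s], ds.annotation, config.min_peak_len, config.flank_bp,
            config.marking_rule,
        )
        for s in sim.samples
    }
    mark_df = pd.DataFrame(
        {s: {g: c.marked for g, c in cs.calls.items()} for s, cs in callsets.items()}
    ).astype(int)
    emit("marking_calls.tsv", mark_df)
    venn = marking.venn_counts([callsets[s] for s in sim.samples])
    venn_df = pd.DataFrame(
        [{**dict(zip(sim.samples, k)), "count": v} for k, v in venn.items()]
    )
    emit("venn_cells.tsv", venn_df, index=False)
    keyed = {(l, t): callsets[f"{l}_{t}"] for l in sim.lines for t in sim.study_tissues}
    stable, specific = marking.stable_and_specific(keyed, sim.lines, sim.study_tissues)
    emit(
        "marked_sets.tsv",
        pd.DataFrame(
            [("stable", g) for g in sorted(stable)]
            + [(f"{t}_specific", g) for t, gs in specific.items() for g in sorted(gs)],
            columns=["set", "gene_id"],
        ),
        index=False,
    )

    # --- differential -------------------------------------------------------
    scales = {
        s: differential.ses_scale_factor(
            ds.coverage[s]["chip"].rebin(config.ses_bin_bp),
            ds.coverage[s]["input"].rebin(config.ses_bin_bp),
        )
        for s in sim.samples
    }
    comparisons = [
        (f"{sim.lines[0]}_{t}", f"{sim.lines[1]}_{t}") for t in sim.study_tissues
    ] + [(f"{sim.lines[0]}_{sim.study_tissues[0]}", f"{sim.lines[0]}_{sim.study_tissues[1]}")]
    diff_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in comparisons:
        df = differential.differential_analysis(
            ds.region_counts, a, b, scales[a], scales[b],
            callsets[a], callsets[b], config.log2_cut, config.q_cut,
        )
        diff_tables[(a, b)] = df
        emit(f"differential_{a}_vs_{b}.tsv", df, index=False)

    # --- expression ---------------------------------------------------------
    expr_table = expression.ExpressionTable(ds.expression)
    groups = pd.DataFrame(
        {s: expression.expression_groups(expr_table, s, config.min_fpkm_for_reads)
         for s in sim.samples}
    )
    emit("expression_groups.tsv", groups)
    chi_rows = []
    for s in sim.samples:
        marked = callsets[s].marked_genes
        obs = groups.loc[groups.index.isin(marked), s].value_counts().to_dict()
        tot = groups[s].value_counts().to_dict()
        stat, p = expression.group_distribution_test(obs, tot)
        chi_rows.append((s, stat, p))
    emit("group_chi2.tsv", pd.DataFrame(chi_rows, columns=["sample", "chi2", "p"]), index=False)
    taus = expression.tau_table(expr_table, list(sim.tissues))
    emit("tau.tsv", taus)
    conc_rows = []
    for (a, b), df in diff_tables.items():
        sig = df[df["significant"]]
        kdir = dict(zip(sig["gene_id"], sig["direction"]))
        deg = {
            g: expression.deg_flag(
                ds.expression.at[g, a], ds.expression.at[g, b], config.deg_epsilon
            )
            for g in kdir
        }
        if kdir:
            classes = expression.mark_expression_concordance(kdir, deg)
            summary = expression.concordance_summary(classes)
            conc_rows.append({"comparison": f"{a}_vs_{b}", **summary})
    emit("concordance.tsv", pd.DataFrame(conc_rows), index=False)

    # --- comparative --------------------------------------------------------
    ref_t = sim.study_tissues[-1]
    marked_ref = set.intersection(
        *(callsets[f"{l}_{ref_t}"].marked_genes for l in sim.lines)
    )
    pclass = comparative.classify_paralogs(marked_ref, ds.annotation.paralog_sets())
    emit("paralog_classes.tsv", pclass.per_set, index=False)
    summary = pd.DataFrame(
        [
            {"metric": "paralogous_conserved", "value": pclass.paralogous_conserved},
            {"metric": "copy_specific", "value": pclass.copy_specific},
            *({"metric": f"three_copy_{k}", "value": v} for k, v in pclass.three_copy.items()),
            *({"metric": f"two_copy_{k}", "value": v} for k, v in pclass.two_copy.items()),
        ]
    )
    emit("paralog_summary.tsv", summary, index=False)
    dens = comparative.snp_density(ds.variants, ds.annotation)
    emit("snp_density.tsv", dens)

    # --- profiles -----------------------------------------------------------
    ref_sample = sim.samples[0]
    stable_genes = [ds.annotation[g] for g in sorted(stable)] or list(ds.annotation)
    prof = profiles.metagene_profile(
        ds.coverage[ref_sample]["chip"], stable_genes, config.metagene_flank_bp
    )
    emit("metagene_stable.tsv",
         pd.DataFrame({"bin": range(len(prof.values)), "rpm_per_bp": prof.values}),
         index=False)
    corr_rows = [
        (a, b, profiles.sample_correlation(ds.region_counts, a, b))
        for i, a in enumerate(sim.samples) for b in sim.samples[i + 1:]
    ]
    emit("sample_correlation.tsv", pd.DataFrame(corr_rows, columns=["a", "b", "pearson_r"]),
         index=False)
    spread_rows = []
    for gid in ds.truth.flc_genes:
        reports, transitions = profiles.spreading_call(
            [(tp, ds.vernalization[tp]) for tp in sim.vernalization_timepoints],
            ds.annotation[gid], config.nucleation_intron_bp,
            config.spreading_e_min, config.spreading_b_spread,
        )
        for tp, rep in reports:
            spread_rows.append(
                (gid, tp, rep.nucleation_enrichment, rep.body_breadth, rep.spreading_call)
            )
    emit("vernalization_spreading.tsv",
         pd.DataFrame(spread_rows,
                      columns=["gene_id", "timepoint", "nucleation_enrichment",
                               "body_breadth", "call"]),
         index=False)

    # --- enrichment ---------------------------------------------------------
    conserved_sets = set(pclass.per_set.loc[
        pclass.per_set["class"].isin(["all_three", "exactly_two", "both"]), "set_id"
    ])
    study = {
        g.gene_id for g in ds.annotation if g.paralog_set_id in conserved_sets
    }
    population = {g.gene_id for g in ds.annotation}
    enr = enrichment.term_enrichment(study, population, ds.terms, config.fdr)
    emit("term_enrichment.tsv", enr)

    # --- manifest -----------------------------------------------------------
    all_files = {**{f"inputs/{k}": v for k, v in input_paths.items()},
                 **outputs}
    manifest = {
        "parameters": {k: v for k, v in asdict(config).items() if k != "simulation"},
        "simulation": asdict(sim),
        "outputs": {name: _sha256(p) for name, p in sorted(all_files.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump({**asdict(config)}, fh, default_flow_style=False)
    return manifest
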