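"""End-to-end study-replica pipeline.

Stages: convert -> classify -> discover -> flag -> component -> date ->
diversity -> fst -> mds -> krige.  Each stage is a pure function of its
inputs and the run configuration; artifacts land in the output directory
in the module-owned text formats, and the run summary is written as JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import geo, haplogroups, nomenclature, popgen
from .dating import CLOCKS, age_from_rho, get_clock, ml_tmrca
from .nomenclature import HaplotypeProfile

log = logging.getLogger("mitophylogeo")


@dataclass
class RunConfig:
    out_dir: str
    tree_path: str | None = None          # None -> bundled toy tree
    vcf_path: str | None = None           # None -> simulate the study
    haplotype_table: str | None = None
    clock: str = "soares-complete"
    flagged_nodes: list[str] = field(default_factory=list)
    home_region: str = "Europe"
    hvs1_range: tuple[int, int] = (16024, 16365)
    seed: int = 0
    n_samples: int = 110
    admixture_fraction: float = 0.082
    krige_sites: str | None = None        # GeoSample TSV

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def validate(self) -> None:
        for p in (self.tree_path, self.vcf_path, self.haplotype_table, self.krige_sites):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if self.clock not in CLOCKS:
            try:
                float(self.clock)
            except (TypeError, ValueError):
                raise ValueError(f"unknown clock {self.clock!r}") from None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("[%s] %s: start", time.strftime("%H:%M:%S"), name)
            out = fn(*args, **kwargs)
            log.info("[%s] %s: done in %.2fs", time.strftime("%H:%M:%S"), name, time.time() - t0)
            return out

        return inner

    return wrap


@dataclass
class RunReport:
    summary: dict
    artifacts: dict[str, str]

    def digest(self) -> str:
        """Stable hash of all artifact contents (determinism check)."""
        h = hashlib.sha256()
        for name in sorted(self.artifacts):
            h.update(Path(self.artifacts[name]).read_bytes())
        return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> RunReport:
    from .simulate import (
        SimulationConfig,
        default_study_populations,
        simulate_admixed_study,
        toy_tree,
        write_fixture_vcf,
    )

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summary: dict = {"seed": cfg.seed}

    # --- tree
    if cfg.tree_path:
        tree = haplogroups.load_tree(Path(cfg.tree_path).read_text())
    else:
        tree = toy_tree()

    # --- input haplotypes (convert stage)
    @_stage("convert")
    def convert() -> list[HaplotypeProfile]:
        if cfg.haplotype_table:
            return nomenclature.read_haplotype_table(cfg.haplotype_table)
        if cfg.vcf_path:
            import pysam

            with pysam.VariantFile(cfg.vcf_path) as vf:
                samples = list(vf.header.samples)
            return [nomenclature.vcf_to_profile(cfg.vcf_path, s) for s in samples]
        sim = SimulationConfig(
            seed=cfg.seed,
            n_samples=cfg.n_samples,
            admixture_fraction=cfg.admixture_fraction,
        )
        pop, truth = simulate_admixed_study(sim)
        summary["simulated_truth_source_count"] = truth.count("source")
        vcf_path = out / "study.vcf"
        write_fixture_vcf(pop.profiles, str(vcf_path))
        artifacts["study_vcf"] = str(vcf_path)
        return list(pop.profiles)

    profiles = convert()
    table_path = out / "haplotypes.tsv"
    nomenclature.write_haplotype_table(profiles, str(table_path))
    artifacts["haplotypes"] = str(table_path)
    summary["n_samples"] = len(profiles)

    # --- classify
    phylo_policy = nomenclature.phylogeny_policy()

    @_stage("classify")
    def classify_all():
        results = []
        for p in profiles:
            filtered = nomenclature.apply_exclusions(p, phylo_policy)
            results.append(haplogroups.classify(filtered, tree)[0])
        return results

    classifications = classify_all()
    cls_path = out / "classifications.tsv"
    with open(cls_path, "w") as fh:
        fh.write("sample\thaplogroup\tscore\tprivate\n")
        for c in classifications:
            fh.write(
                f"{c.sample_id}\t{c.best_node}\t{c.score:.4f}\t"
                + "-".join(v.render() for v in c.private)
                + "\n"
            )
    artifacts["classifications"] = str(cls_path)
    tallies: dict[str, int] = {}
    for c in classifications:
        tallies[c.best_node] = tallies.get(c.best_node, 0) + 1
    summary["haplogroup_tallies"] = dict(sorted(tallies.items()))

    # --- discover new subclades under each occupied node
    @_stage("discover")
    def discover():
        by_node: dict[str, list[HaplotypeProfile]] = {}
        for p, c in zip(profiles, classifications):
            by_node.setdefault(c.best_node, []).append(
                nomenclature.apply_exclusions(p, phylo_policy)
            )
        proposals = []
        for name, members in sorted(by_node.items()):
            if len(members) < 2:
                continue
            parent_state = haplogroups.node_state_profile(tree, name)
            for node in haplogroups.discover_subclades(
                members, parent_state, parent_name=name
            ):
                proposals.append(node)
        return proposals

    proposals = discover()
    disc_path = out / "proposed_clades.tsv"
    with open(disc_path, "w") as fh:
        fh.write("name\tdefining\tmembers\n")
        for node, _ in [(n, 0) for p in proposals for n, _ in p.walk()]:
            fh.write(
                f"{node.name}\t"
                + ",".join(v.render() for v in node.defining_variants)
                + "\t"
                + ",".join(node.annotations.get("members", []))
                + "\n"
            )
    artifacts["proposed_clades"] = str(disc_path)
    summary["proposed_clades"] = sum(len(list(p.walk())) for p in proposals)

    # --- flagged clades and the ancestry component
    flagged = set(cfg.flagged_nodes)
    if not flagged:
        _specs, flagged, _src = default_study_populations()
    component = haplogroups.ancestry_component(classifications, flagged, tree=tree)
    summary["flagged_nodes"] = sorted(flagged)
    summary["ancestry_component_pct"] = round(component, 1)

    # --- dating of the flagged clades present in the data
    clock = get_clock(cfg.clock)

    @_stage("date")
    def date():
        from .dating import star_genealogy

        ages = {}
        states = haplogroups.cumulative_states(tree)
        for name in sorted(flagged):
            members = [
                nomenclature.apply_exclusions(p, phylo_policy)
                for p, c in zip(profiles, classifications)
                if c.best_node in tree.descendant_names(name)
            ]
            if len(members) < 2:
                continue
            root_prof = haplogroups.node_state_profile(tree, name)
            dists = [popgen.haplotype_distance(m, root_prof) for m in members]
            g = star_genealogy(dists, [m.sample_id for m in members])
            est_rho = age_from_rho(g, clock)
            est_ml = ml_tmrca(g, clock)
            ages[name] = {
                "n": len(members),
                "rho": est_rho.rho_or_ml,
                "age_rho": est_rho.age_years,
                "ci_rho": [est_rho.ci95_low, est_rho.ci95_high],
                "age_ml": est_ml.age_years,
                "ci_ml": [est_ml.ci95_low, est_ml.ci95_high],
            }
        return ages

    summary["clade_ages"] = date()

    # --- diversity on the HVS-I segment
    div_policy = nomenclature.diversity_policy()
    lo, hi = cfg.hvs1_range
    hvs1 = [
        nomenclature.apply_exclusions(nomenclature.restrict_range(p, lo, hi), div_policy)
        for p in profiles
    ]
    study_pop = popgen.PopulationSet(label="study", profiles=hvs1, region=cfg.home_region)
    rep = popgen.diversity(study_pop)
    summary["diversity"] = {"HD": rep.HD, "pi": rep.pi, "M": rep.M, "n": rep.n, "L": rep.L}
    div_path = out / "diversity.tsv"
    with open(div_path, "w") as fh:
        fh.write("population\tn\tHD\tpi\tM\tL\n")
        fh.write(f"study\t{rep.n}\t{rep.HD:.4f}\t{rep.pi:.6f}\t{rep.M:.4f}\t{rep.L}\n")
    artifacts["diversity"] = str(div_path)

    # --- Phi_ST + MDS against simulated comparison populations
    @_stage("fst_mds")
    def fst_mds():
        from .simulate import SimulationConfig as SC, simulate_haplotype_for, toy_tree as tt

        rng = np.random.default_rng(cfg.seed + 1)
        states = haplogroups.cumulative_states(tree)
        pools = {
            "Europe": {"H": 0.5, "HV": 0.2, "J": 0.15, "T2": 0.15},
            "Caucasus": {"U7a4": 0.4, "HV9": 0.3, "T2": 0.3},
            "NearEast": {"U7a4a1a": 0.35, "J1d": 0.35, "HV9c": 0.3},
        }
        sim = SC(seed=cfg.seed)
        pops = [study_pop]
        for label, pool in pools.items():
            members = []
            for i in range(24):
                names = sorted(pool)
                probs = np.array([pool[k] for k in names])
                hg = names[rng.choice(len(names), p=probs)]
                prof = simulate_haplotype_for(hg, states, sim, rng, f"{label}{i:02d}")
                prof = nomenclature.apply_exclusions(
                    nomenclature.restrict_range(prof, lo, hi), div_policy
                )
                members.append(prof)
            pops.append(popgen.PopulationSet(label=label, profiles=members, region=label))
        dmat = popgen.fst_matrix(pops)
        mds = popgen.classical_mds(dmat, k=2)
        return dmat, mds

    dmat, mds = fst_mds()
    fst_path = out / "phist_matrix.tsv"
    dmat.to_tsv(str(fst_path))
    artifacts["phist_matrix"] = str(fst_path)
    mds_path = out / "mds_coordinates.tsv"
    with open(mds_path, "w") as fh:
        fh.write(
            "# variance fractions: "
            + " ".join(f"{f:.4f}" for f in mds.variance_fraction)
            + "\n"
        )
        fh.write("population\tdim1\tdim2\n")
        for lab, row in zip(mds.labels, mds.coordinates):
            fh.write(f"{lab}\t{row[0]:.6f}\t{row[1]:.6f}\n")
    artifacts["mds"] = str(mds_path)
    summary["mds_variance_fractions"] = [round(float(f), 4) for f in mds.variance_fraction]
    summary["phist"] = {
        f"{a}|{b}": float(dmat.values[i, j])
        for i, a in enumerate(dmat.labels)
        for j, b in enumerate(dmat.labels)
        if i < j
    }

    # --- kriged frequency surface
    @_stage("krige")
    def krige():
        if cfg.krige_sites:
            samples = geo.read_geosamples_tsv(cfg.krige_sites, is_frequency=True)
        else:
            rng = np.random.default_rng(cfg.seed + 2)
            # synthetic sampling sites spanning Europe to Iran with an
            # eastward frequency rise, mimicking a source-region clade
            lons = rng.uniform(5, 55, 16)
            lats = rng.uniform(32, 48, 16)
            vals = np.clip((lons - 5) / 50 * 0.3 + rng.normal(0, 0.02, 16), 0, 1)
            samples = [
                geo.GeoSample(lon=lo_, lat=la_, value=v, label=f"site{i}", is_frequency=True)
                for i, (lo_, la_, v) in enumerate(zip(lons, lats, vals))
            ]
        model = geo.fit_variogram(samples, family="exponential", nugget=0.0)
        glons, glats = geo.default_grid(samples, n=20)
        return samples, geo.ordinary_krige(samples, model, glons, glats)

    samples, surface = krige()
    surf_path = out / "frequency_surface.tsv"
    surface.to_tsv(str(surf_path))
    artifacts["surface"] = str(surf_path)
    summary["krige_weight_sum_error"] = float(surface.weight_sum_error)

    report = RunReport(summary=summary, artifacts=artifacts)
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    artifacts["summary"] = str(summary_path)
    return report
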