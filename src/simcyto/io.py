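"""File formats and the end-to-end pipeline.

Genotype tables are TSV (UTF-8, header mandatory): ``larva_id``, ``site``,
``species``, ``sex``, ``sex_config``, optional ``flags`` (semicolon
separated), then one column per rearrangement holding 0/1/2 or NA.  Reports
are TSV; trees are Newick.  Reads and writes round-trip exactly, and two
pipeline runs with the same configuration and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

from . import __version__
from .karyotype import Registry, RegistryError, load_registry
from .popgen import (FrequencyTable, LarvaRecord, classify_linkage,
                     frequency_table, genotype_counts, hw_test,
                     hybrid_screen, sex_chromosome_census,
                     shared_rearrangement_accounting, DegenerateTestError)
from .phylogeny import Cladogram

META_COLUMNS = ("larva_id", "site", "species", "sex", "sex_config", "flags")


class ParseError(ValueError):
    pass


def read_genotype_table(path, registry: Registry | None = None) -> list[LarvaRecord]:
    """Read a per-larva genotype TSV; malformed rows raise line-numbered
    errors, and unknown rearrangement columns are rejected when a registry
    is supplied."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    for col in META_COLUMNS[:5]:
        if col not in header:
            raise ParseError(f"{path}:1: missing required column {col!r}")
    names = [c for c in header if c not in META_COLUMNS]
    if registry is not None:
        unknown = [n for n in names if n not in registry]
        if unknown:
            raise RegistryError(f"{path}: unknown rearrangement columns {unknown}")
    idx = {c: header.index(c) for c in header}
    records = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(f"{path}:{ln}: expected {len(header)} fields, got {len(cells)}")
        try:
            genotypes = {}
            for name in names:
                raw = cells[idx[name]]
                genotypes[name] = None if raw == "NA" else int(raw)
            flags = frozenset()
            if "flags" in idx and cells[idx["flags"]]:
                flags = frozenset(cells[idx["flags"]].split(";"))
            records.append(LarvaRecord(
                larva_id=cells[idx["larva_id"]],
                site=int(cells[idx["site"]]),
                species=cells[idx["species"]],
                sex=cells[idx["sex"]],
                genotypes=genotypes,
                sex_config=cells[idx["sex_config"]],
                flags=flags))
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}:{ln}: {exc}") from exc
    return records


def write_genotype_table(records, path) -> None:
    names: dict[str, None] = {}
    for rec in records:
        for n in rec.genotypes:
            names.setdefault(n)
    names = list(names)
    rows = ["\t".join(META_COLUMNS + tuple(names))]
    for rec in records:
        cells = [rec.larva_id, str(rec.site), rec.species, rec.sex,
                 rec.sex_config, ";".join(sorted(rec.flags))]
        for n in names:
            g = rec.genotypes.get(n)
            cells.append("NA" if g is None else str(g))
        rows.append("\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def write_frequency_report(table: FrequencyTable, path) -> None:
    """Frequency survey layout: one row per rearrangement, one column per
    species x site, blank cells for absence and categorical marks for
    sex-linked entries."""
    header = ["rearrangement"] + [f"{sp} site {site}" for sp, site in table.groups]
    rows = ["\t".join(header)]
    for name in table.names:
        rows.append("\t".join([name] + [table.cell_text(name, g) for g in table.groups]))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def write_newick(cladogram: Cladogram, path, order=None) -> None:
    """Write the cladogram with branch-support counts as Newick comments."""
    tree = dendropy.Tree.get(data=cladogram.newick(order), schema="newick")
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        chars = cladogram.support.get(leaves)
        if chars and len(leaves) > 1:
            node.label = f"[{len(chars)} synapomorphies]"
    Path(path).write_text(tree.as_string(schema="newick"), encoding="utf-8")


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    output_dir: Path
    genotype_path: Path | None = None      # default: the packaged lineage survey
    seed: int = 0
    run_simulation: bool = False
    simulation_replicates: int = 2000
    verbosity: int = 1
    log_stream: object = field(default_factory=lambda: sys.stderr)


def run_pipeline(config: PipelineConfig) -> int:
    """derive -> frequencies -> HW -> linkage -> census -> hybrids -> phylogeny
    (optionally -> simulate); writes all reports plus a run log."""
    from . import lineage
    from .karyotype import DerivationScenario, verify_derivation
    from .phylogeny import infer_tree, polarize
    from .fixation import SimulationConfig, simulate_trajectory
    import json

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"simcyto {__version__}", f"seed {config.seed}"]

    def log(msg):
        log_lines.append(msg)
        if config.verbosity:
            print(msg, file=config.log_stream)

    registry = load_registry()
    if config.genotype_path is not None:
        records = read_genotype_table(config.genotype_path)
        log(f"read {len(records)} records from {config.genotype_path}")
    else:
        records = lineage.build_records()
        log(f"built {len(records)} packaged lineage records")

    # derivations
    import importlib.resources as resources
    doc = json.loads(resources.files("simcyto.data").joinpath("scenarios.json").read_text())
    derive_rows = ["taxon\tarm\tsequence\tsteps\tverified\tfragments"]
    for scn in doc["scenarios"]:
        scenario = DerivationScenario(scn["start_label"], scn["arm"],
                                      tuple(scn["steps"]), tuple(scn["end_tokens"]))
        ok, frags = verify_derivation(scenario, registry)
        derive_rows.append("\t".join([scn["taxon"], scn["arm"], scn["sequence"],
                                      ",".join(scn["steps"]), str(ok), str(len(frags))]))
    (out / "derivations.tsv").write_text("\n".join(derive_rows) + "\n", encoding="utf-8")
    log(f"verified {len(doc['scenarios'])} derivation scenarios")

    table = frequency_table(records, lineage.ALL_NAMES
                            if config.genotype_path is None else None)
    write_frequency_report(table, out / "frequencies.tsv")

    # Hardy-Weinberg for common polymorphisms (pooled per species)
    hw_rows = ["species\trearrangement\tss\tsi\tii\tallele_freq\tchi_square\tdf\tp_value\treject"]
    species_list = sorted({r.species for r in records})
    for sp in species_list:
        sub = [r for r in records if r.species == sp]
        for name in table.names:
            ss, si, ii = genotype_counts(sub, name)
            n = ss + si + ii
            if n == 0 or si + ii == 0 or ss + si == 0:
                continue
            freq = (si + 2 * ii) / (2 * n)
            if not 0.1 <= freq <= 0.9:
                continue
            try:
                res = hw_test(ss, si, ii)
            except DegenerateTestError:
                continue
            hw_rows.append("\t".join(map(str, [sp, name, ss, si, ii,
                                               f"{float(res.allele_freq):.4f}",
                                               f"{res.chi_square:.4f}", res.df,
                                               f"{res.p_value:.4f}", res.reject])))
    (out / "hardy_weinberg.tsv").write_text("\n".join(hw_rows) + "\n", encoding="utf-8")

    link_rows = ["species\trearrangement\tcall"]
    for sp in species_list:
        sub = [r for r in records if r.species == sp]
        for name in table.names:
            call = classify_linkage(sub, name)
            if call.call not in ("autosomal_polymorphic", "indeterminate"):
                link_rows.append(f"{sp}\t{name}\t{call.call}")
    (out / "linkage.tsv").write_text("\n".join(link_rows) + "\n", encoding="utf-8")

    census_rows = ["species\tsex\tconfiguration\tcount\tpercent"]
    for sp in species_list:
        census = sex_chromosome_census(records, sp)
        for sex in ("female", "male"):
            for cfg, (k, pct) in census[sex].items():
                census_rows.append(f"{sp}\t{sex}\t{cfg}\t{k}\t{float(pct):.1f}")
    (out / "census.tsv").write_text("\n".join(census_rows) + "\n", encoding="utf-8")

    sympatric = [r for r in records
                 if r.species in ("cholodkovskii", "decimatum")]
    screen = hybrid_screen(sympatric, lineage.DIAGNOSTICS_CHOLODKOVSKII,
                           lineage.DIAGNOSTICS_DECIMATUM)
    hyb_rows = ["larva_id\thet_A\thet_B\tcompleteness\tfull_hybrid"]
    for c in screen.candidates:
        hyb_rows.append("\t".join([c.larva_id, ",".join(c.het_a), ",".join(c.het_b),
                                   f"{float(c.completeness):.2f}", str(c.full)]))
    (out / "hybrid_screen.tsv").write_text("\n".join(hyb_rows) + "\n", encoding="utf-8")
    log(f"hybrid screen: {len(screen.candidates)} candidate(s) among {screen.n_screened} larvae")

    matrix = lineage.character_matrix(table)
    polarize(matrix)
    clad = infer_tree(matrix)
    write_newick(clad, out / "cytophylogeny.nwk", order=matrix.ingroup)
    distinct, shared, shared_poly = shared_rearrangement_accounting(
        table, ("cholodkovskii", "decimatum"))
    log(f"phylogeny score {clad.score}; ties {len(clad.ties)}; "
        f"shared accounting {distinct}/{shared}/{shared_poly}")

    if config.run_simulation:
        sim = simulate_trajectory(SimulationConfig(
            replicates=config.simulation_replicates, seed=config.seed))
        sim_rows = ["generation\tfreq_typical\tfreq_het\tfreq_hom"]
        for gen, ft, fh, fo in sim.trajectories[0]:
            sim_rows.append(f"{int(gen)}\t{ft:.4f}\t{fh:.4f}\t{fo:.4f}")
        (out / "simulation_trajectory.tsv").write_text("\n".join(sim_rows) + "\n",
                                                       encoding="utf-8")
        log(f"fixation probability {sim.fixation_probability:.4f} "
            f"over {config.simulation_replicates} replicates")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return 0
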