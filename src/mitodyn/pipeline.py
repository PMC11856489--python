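"""End-to-end orchestration: run every analysis stage over a cohort of
annotated mitogenomes and write deterministic TSV/JSON outputs plus a
manifest recording parameters and input checksums."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_usage import census_start_stop, census_table, count_codons, rscu, rscu_table
from .composition import (composition_table, decompose, decomposition_table,
                          find_dispersed_repeats, find_tandem_repeats, repeat_table)
from .evol_rates import (mean_distance_matrix, nj_tree, pairwise_rates_table,
                         summarize_gene, write_phylip)
from .gene_order_synteny import (block_table, breakpoint_distance, extract_order,
                                 find_blocks, group_arrangements, order_table)
from .genome_io import CORE_PCGS, MitogenomeRecord, extract_cds, read_genbank, write_tables
from .intron_dynamics import (classify, cluster_ips, extract_introns, flank_profile,
                              intron_table, ips_table, map_all)
from .size_correlation import regress_components
from .synthetic_data import make_fixture

log = logging.getLogger("mitodyn")

GENE_SETS = {"15": list(CORE_PCGS), "14": [g for g in CORE_PCGS if g != "rps3"]}


@dataclass
class PipelineConfig:
    inputs: list[str] = field(default_factory=list)   # GenBank paths
    fixture: str | None = None                        # or a named synthetic cohort
    reference_species: str | None = None              # default: first record
    tolerance: int = 3
    gene_set: str = "15"
    min_block_len: int = 500
    min_block_identity: float = 0.7
    tandem_min_unit: int = 10
    tandem_max_unit: int = 200
    dispersed_min_len: int = 35
    dispersed_min_identity: float = 0.76
    outdir: str = "mitodyn_out"
    seed: int = 1729


def load_records(config: PipelineConfig) -> list[MitogenomeRecord]:
    if config.fixture:
        records, _ = make_fixture(config.fixture)
        return records
    records = []
    for path in config.inputs:
        records.extend(read_genbank(path))
    if not records:
        raise ValueError("no input records: give GenBank paths or a fixture name")
    return records


def _cds_by_gene(records, genes) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for rec in records:
        for gene in genes:
            if rec.get_gene(gene) is not None:
                out.setdefault(gene, {})[rec.id] = extract_cds(rec, gene)
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to
    ``manifest.json``).  Comparative stages are skipped with a logged
    notice when fewer than two genomes are supplied."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = load_records(config)
    reference = config.reference_species or records[0].id
    genes = GENE_SETS[str(config.gene_set)]
    stages: list[str] = []

    stages.append(run_composition(records, outdir, config))
    stages.append(run_codons(records, outdir, genes))
    if len(records) >= 2:
        stages.append(run_distances(records, outdir, genes))
        stages.append(run_introns(records, outdir, reference, config.tolerance))
        stages.append(run_order_synteny(records, outdir, config))
        if len(records) >= 3:
            stages.append(run_correlation(records, outdir))
        else:
            log.info("stage\tcorrelate\tskipped\tfewer than 3 genomes")
    else:
        for st in ("distances", "introns", "order_synteny", "correlate"):
            log.info("stage\t%s\tskipped\tsingle-genome input", st)

    params = asdict(config)
    params.pop("outdir")  # implied by the manifest's own location
    manifest = {
        "package": "mitodyn",
        "version": __version__,
        "stages_complete": stages,
        "parameters": params,
        "reference_species": reference,
        "n_genomes": len(records),
        "input_checksums": {r.id: hashlib.sha256(r.sequence.encode()).hexdigest()
                            for r in records},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_composition(records, outdir: Path, config: PipelineConfig) -> str:
    write_tables(composition_table(records), outdir / "composition.tsv")
    write_tables(decomposition_table(records), outdir / "components.tsv")
    frames = []
    for rec in records:
        tandem = find_tandem_repeats(rec.sequence, config.tandem_min_unit,
                                     config.tandem_max_unit)
        dispersed = find_dispersed_repeats(rec, config.dispersed_min_len,
                                           config.dispersed_min_identity)
        frames.append(repeat_table(rec.id, tandem + dispersed))
    write_tables(pd.concat(frames, ignore_index=True) if frames else repeat_table("", []),
                 outdir / "repeats.tsv")
    log.info("stage\tcomposition\tcomplete\t%d genomes", len(records))
    return "composition"


def run_codons(records, outdir: Path, genes) -> str:
    tables, censuses = [], []
    for rec in records:
        cds_set = [extract_cds(rec, g) for g in genes if rec.get_gene(g) is not None]
        tables.append(rscu(count_codons(cds_set, species_id=rec.id)))
        censuses.append(census_start_stop(cds_set))
    write_tables(rscu_table(tables), outdir / "rscu.tsv")
    merged = censuses[0]
    for c in censuses[1:]:
        merged.entries.update(c.entries)
    write_tables(census_table(merged), outdir / "start_stop.tsv")
    log.info("stage\tcodon_usage\tcomplete\t%d genomes", len(records))
    return "codon_usage"


def run_distances(records, outdir: Path, genes) -> str:
    cds = _cds_by_gene(records, genes)
    rates = pairwise_rates_table(cds)
    write_tables(rates, outdir / "rates.tsv")
    write_tables(summarize_gene(rates, "k2p"), outdir / "k2p_by_gene.tsv")
    write_tables(summarize_gene(rates, "ka_ks"), outdir / "kaks_by_gene.tsv")
    dm = mean_distance_matrix(rates)
    write_phylip(dm, outdir / "distances.phylip")
    if len(dm.labels) >= 3:
        (outdir / "nj.nwk").write_text(nj_tree(dm) + "\n")
    log.info("stage\tevol_rates\tcomplete\t%d pairs", len(rates))
    return "evol_rates"


def run_introns(records, outdir: Path, reference: str, tolerance: int) -> str:
    introns = [i for rec in records for i in extract_introns(rec)]
    host_genes = sorted({i.host_gene for i in introns})
    cds = _cds_by_gene(records, host_genes)
    mapped = map_all(introns, cds, reference)
    catalog = cluster_ips(mapped, tolerance=tolerance, reference_species=reference)
    write_tables(intron_table(mapped), outdir / "introns.tsv")
    write_tables(ips_table(catalog), outdir / "ips.tsv")
    write_tables(catalog.presence_absence(), outdir / "ips_presence.tsv")
    summary = classify(catalog)
    shared = [ips for ips in catalog.ips_list if ips.shared]
    profiles = {}
    for ips in shared:
        members = [m for v in ips.members.values() for m in v]
        freq, consensus, dinucs = flank_profile(members)
        profiles[ips.id] = {"consensus": consensus, "dinucleotides": dinucs,
                            "pfm": {str(p): freq[p].round(4).tolist()
                                    for p in freq.columns}}
    with open(outdir / "introns_summary.json", "w") as fh:
        json.dump({"summary": summary, "flank_profiles": profiles}, fh,
                  indent=2, sort_keys=True, default=str)
    log.info("stage\tintron_dynamics\tcomplete\t%d introns, %d IPS",
             len(mapped), summary["n_ips"])
    return "intron_dynamics"


def run_order_synteny(records, outdir: Path, config: PipelineConfig) -> str:
    orders = [extract_order(r) for r in records]
    write_tables(order_table(orders), outdir / "gene_order.tsv")
    classes = group_arrangements(orders)
    rows = []
    for i, a in enumerate(orders):
        for b in orders[i + 1:]:
            rows.append({"species_a": a.species_id, "species_b": b.species_id,
                         "breakpoints": breakpoint_distance(a, b)})
    write_tables(pd.DataFrame(rows, columns=["species_a", "species_b", "breakpoints"]),
                 outdir / "breakpoints.tsv")
    frames = []
    for i, ra in enumerate(records):
        for rb in records[i + 1:]:
            frames.append(block_table(find_blocks(ra, rb, config.min_block_len,
                                                  config.min_block_identity)))
    blocks = pd.concat(frames, ignore_index=True) if frames else block_table([])
    write_tables(blocks, outdir / "synteny_blocks.tsv")
    links = blocks[["species_a", "start_a", "end_a", "species_b", "start_b", "end_b"]]
    write_tables(links, outdir / "synteny_links.tsv")
    log.info("stage\tgene_order_synteny\tcomplete\t%d arrangement classes", len(classes))
    return "gene_order_synteny"


def run_correlation(records, outdir: Path) -> str:
    decomps = [decompose(r) for r in records]
    write_tables(regress_components(decomps), outdir / "size_correlation.tsv")
    log.info("stage\tsize_correlation\tcomplete\t%d genomes", len(records))
    return "size_correlation"
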