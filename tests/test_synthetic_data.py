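"""Planted structure of the synthetic generators: reproducibility, DAG
well-formedness, annotation coherence, contact decay/TAD enrichment and
expression modules."""

import numpy as np
import pytest

from tadfunc.genome_model import GenomicInterval
from tadfunc.pair_analysis import filter_duplicates, gess, GenePair
from tadfunc.synthetic_data import (
    SimConfig,
    derive_seed,
    make_contacts,
    make_expression,
    make_genome,
    simulate,
)


class TestGenome:
    def test_fixed_seed_reproducible(self):
        a = make_genome(SimConfig(seed=5))
        b = make_genome(SimConfig(seed=5))
        assert [t.interval for t in a.tads] == [t.interval for t in b.tads]
        assert [(g.id, g.interval) for g in a.genes] == [(g.id, g.interval) for g in b.genes]

    def test_tads_non_overlapping_scan_oracle(self):
        g = make_genome(SimConfig(seed=1))
        ivs = sorted((t.interval.start, t.interval.end) for t in g.tads)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2

    def test_requested_counts_honoured(self):
        cfg = SimConfig(seed=2, n_tads=7, n_genes=150)
        g = make_genome(cfg)
        assert len(g.tads) == 7 and len(g.genes) == 150

    def test_boundary_genes_excluded_by_assignment(self, dataset):
        excluded = [
            gid for gid, a in dataset.partition.assignment.items()
            if a.status == "excluded"
        ]
        n_boundary = int(round(dataset.config.boundary_gene_fraction * dataset.config.n_genes))
        assert len(excluded) >= n_boundary


class TestOntology:
    def test_every_term_reaches_its_root(self, dataset):
        dag = dataset.dag
        roots = {"GO:0008150", "GO:0005575", "GO:0003674"}
        for term in dag.namespace:
            seen, frontier = set(), [term]
            while frontier:
                t = frontier.pop()
                if t in seen:
                    continue
                seen.add(t)
                frontier.extend(p for p, _r in dag.parents.get(t, []))
            assert seen & roots, f"{term} cannot reach a namespace root"

    def test_no_root_annotations(self, dataset):
        roots = {"GO:0008150", "GO:0005575", "GO:0003674"}
        for anns in dataset.annotations.annotations.values():
            assert not {t for t, _c in anns} & roots

    def test_module_term_frequency_tracks_p_intra(self, dataset):
        """Across TAD genes, the fraction of annotation draws landing in
        the gene's own module clique approximates p_intra."""
        module_terms = {
            m: set(ts) for m, ts in dataset.ontology.module_terms.items()
        }
        hits, total = 0, 0
        for gene, module in dataset.ontology.module_of_gene.items():
            if module is None:
                continue
            for term, _c in dataset.annotations.annotations[gene]:
                total += 1
                if term in module_terms[module]:
                    hits += 1
        assert total > 500
        # de-duplication of repeated module draws biases slightly low
        assert hits / total == pytest.approx(dataset.config.p_intra, abs=0.08)


class TestContacts:
    def test_symmetric_and_reproducible(self):
        cfg = SimConfig(seed=3)
        genome = make_genome(cfg)
        raw1, norm1 = make_contacts(cfg, genome)
        raw2, _ = make_contacts(cfg, genome)
        assert raw1.entries == raw2.entries
        assert raw1.get(3, 10) == raw1.get(10, 3)

    def test_mean_count_decreases_with_distance(self, dataset):
        by_d = {}
        for (i, j), c in dataset.raw_contacts.entries.items():
            by_d.setdefault(j - i, []).append(c)
        dists = sorted(d for d in by_d if len(by_d[d]) >= 20)
        means = np.array([np.mean(by_d[d]) for d in dists])
        slope = np.polyfit(np.log(dists), np.log(means + 1e-9), 1)[0]
        assert slope < 0

    def test_within_tad_enriched_at_matched_distance(self, dataset):
        res = dataset.config.resolution
        tad_of = {}
        for t in dataset.genome.tads:
            for b in range(t.interval.start // res, (t.interval.end - 1) // res + 1):
                tad_of[b] = t.ordinal
        same, cross = {}, {}
        for (i, j), c in dataset.raw_contacts.entries.items():
            d = j - i
            if d == 0 or d > 15:
                continue
            ti, tj = tad_of.get(i), tad_of.get(j)
            if ti is None or tj is None:
                continue
            (same if ti == tj else cross).setdefault(d, []).append(c)
        ratios = [
            np.mean(same[d]) / np.mean(cross[d])
            for d in same if d in cross and len(cross[d]) >= 10
        ]
        assert np.mean(ratios) > 1.5

    def test_planted_loop_regions_reach_strong_threshold(self, dataset):
        from tadfunc.longrange_regions import classify_region_pairs

        rps = classify_region_pairs(dataset.norm_contacts, 2_000_000)
        strong_bins = {
            (r.bin_a.start, r.bin_b.start) for r in rps if r.label == "strong"
        }
        assert strong_bins  # the planted loops survive normalisation


class TestExpression:
    def test_nonnegative_and_reproducible(self, dataset):
        assert all(v >= 0 for v in dataset.expression.values())
        again = make_expression(dataset.config, dataset.ontology)
        assert again == dataset.expression

    def test_same_module_pairs_have_higher_gess(self, dataset):
        ec = dataset.expression
        lo, hi = min(ec.values()), max(ec.values())
        module = dataset.ontology.module_of_gene
        genes = [g for g, m in module.items() if m is not None]
        rng = np.random.default_rng(0)
        same, cross = [], []
        for _ in range(400):
            a, b = (genes[int(x)] for x in rng.integers(0, len(genes), 2))
            if a == b:
                continue
            s = gess(ec[a], ec[b], hi, lo)
            (same if module[a] == module[b] else cross).append(s)
        assert len(same) > 20 and len(cross) > 20
        assert np.mean(same) > np.mean(cross)


class TestIdentityTable:
    def test_planted_duplicates_all_removed(self, dataset):
        pairs = [GenePair(a, b) for a, b in dataset.planted_duplicates]
        assert filter_duplicates(pairs, dataset.identity_table) == []

    def test_background_pairs_all_kept(self, dataset):
        background = [
            GenePair(a, b)
            for (a, b) in dataset.identity_table
            if (a, b) not in dataset.planted_duplicates
        ]
        assert len(filter_duplicates(background, dataset.identity_table)) == len(background)

    def test_planted_count_matches_config(self, dataset):
        expected = int(round(dataset.config.duplicate_fraction * dataset.config.n_genes))
        assert len(dataset.planted_duplicates) == expected


class TestConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_intra=1.5)

    def test_negative_control_removes_structure(self):
        neg = SimConfig(seed=0).negative_control()
        assert neg.p_intra == neg.p_inter
        assert neg.beta == 1.0 and neg.loops == ()

    def test_derived_seeds_distinct_and_stable(self):
        s1 = derive_seed(0, "contacts")
        s2 = derive_seed(0, "ontology")
        assert s1 != s2
        assert derive_seed(0, "contacts") == s1
        assert 0 <= s1 < 2**31


def test_file_round_trip(tmp_path, dataset):
    """Emitted files parse back through the package readers."""
    from tadfunc.genome_model import read_genes_bed, read_tads
    from tadfunc.ggsi_networks import ContactMatrix
    from tadfunc.pair_analysis import read_expression, read_gmt, read_identity_table

    paths = dataset.write(tmp_path)
    tads = read_tads(paths["tads"])
    assert [t.interval for t in tads] == [t.interval for t in dataset.genome.tads]
    genes = read_genes_bed(paths["genes"])
    assert len(genes) == len(dataset.genome.genes)
    m = ContactMatrix.from_tsv(paths["raw_contacts"], dataset.config.chrom, dataset.config.resolution)
    assert m.entries == dataset.raw_contacts.entries
    expr = read_expression(paths["expression"])
    assert expr.keys() == dataset.expression.keys()
    ident = read_identity_table(paths["identity"])
    assert set(ident) == set(dataset.identity_table)
    gmt = read_gmt(paths["pathways"])
    assert gmt == dataset.pathway_map()
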