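"""Amplicon prediction vs a brute-force matcher, and diagnostic calls."""

from __future__ import annotations

import numpy as np
import pytest

from mule_unmask import (
    DiagnosticScheme,
    LocusConfig,
    Primer,
    amplify,
    build_locus,
    call_genotype,
    design_diagnostic,
    run_diagnostic,
)
from mule_unmask.insilico_pcr import bands_from_amplicons, forward_sites, reverse_sites
from mule_unmask.util import random_seq, revcomp


def brute_force_sites(template, site_seq, exact_offsets, budget):
    out = []
    k = len(site_seq)
    for i in range(len(template) - k + 1):
        window = template[i : i + k]
        if any(window[j] != site_seq[j] for j in exact_offsets):
            continue
        if sum(a != b for a, b in zip(window, site_seq)) <= budget:
            out.append(i)
    return out


def test_end_to_end_length_arithmetic():
    rng = np.random.default_rng(1)
    template = random_seq(100, rng)
    fwd = Primer("F", template[0:20])
    rev = Primer("R", revcomp(template[80:100]))
    (amp,) = amplify({"t": template}, [(fwd, rev)])
    assert (amp.start, amp.end, amp.length) == (0, 100, 100)


def test_inserted_spacer_shifts_length_exactly():
    rng = np.random.default_rng(2)
    template = random_seq(400, rng)
    fwd = Primer("F", template[10:30])
    rev = Primer("R", revcomp(template[300:320]))
    (amp,) = amplify({"t": template}, [(fwd, rev)])
    spaced = template[:150] + random_seq(57, rng) + template[150:]
    (amp2,) = amplify({"t": spaced}, [(fwd, rev)])
    assert amp2.length == amp.length + 57


def test_mismatch_budget_and_anchor():
    """One internal mismatch within budget amplifies; the same mismatch in
    the 3' anchor kills the site."""
    rng = np.random.default_rng(3)
    template = random_seq(300, rng)
    site = template[50:70]
    internal = site[:5] + ("A" if site[5] != "A" else "C") + site[6:]
    fwd_ok = Primer("F1", internal, allowed_mismatches=1, three_prime_anchor=3)
    assert forward_sites(template, fwd_ok) == [50]
    anchor_hit = site[:19] + ("A" if site[19] != "A" else "C")
    fwd_bad = Primer("F2", anchor_hit, allowed_mismatches=1, three_prime_anchor=3)
    assert forward_sites(template, fwd_bad) == []


def test_sites_equal_bruteforce_matcher():
    rng = np.random.default_rng(4)
    for _ in range(10):
        template = random_seq(2000, rng)
        i = int(rng.integers(0, 1980))
        primer_seq = template[i : i + 20]
        p = Primer("P", primer_seq, allowed_mismatches=1, three_prime_anchor=3)
        exact = list(range(17, 20))
        assert forward_sites(template, p) == brute_force_sites(
            template, primer_seq, exact, 1
        )
        r = Primer("R", revcomp(primer_seq), allowed_mismatches=1, three_prime_anchor=3)
        assert reverse_sites(template, r) == brute_force_sites(
            template, primer_seq, list(range(3)), 1
        )


def test_insertion_specific_primer_gives_no_wildtype_product(truth62):
    scheme = design_diagnostic(truth62)
    wt_templates = {"S": truth62.reference_seq}
    _, bands = run_diagnostic(wt_templates, scheme)
    assert "MT_F2+R1" not in bands and "MT_F2+R2" not in bands
    assert bands["WT_F1+R1"] == [327]


def test_diagnostic_reproduces_published_product_sizes(truth62):
    scheme = design_diagnostic(truth62)
    templates = {
        h.name: truth62.hap_genome(i) for i, h in enumerate(truth62.haplotypes)
    }
    call, bands = run_diagnostic(templates, scheme)
    assert call == "present"
    assert bands["MT_F2+R1"] == [326]
    assert bands["MT_F2+R2"] == [276]
    assert bands["WT_F1+R1"] == [327]


@pytest.mark.parametrize(
    "bands,expected",
    [
        ({"MT_F2+R1": 326, "MT_F2+R2": 276, "WT_F1+R1": 327}, "present"),
        ({"WT_F1+R1": 327}, "absent"),
        ({}, "invalid"),
        ({"WT_F1+R1": 500}, "invalid"),  # wrong-size band is no control
        ({"MT_F2+R1": 328}, "present"),  # within the +/-5 size tolerance
    ],
)
def test_band_pattern_calls(bands, expected):
    scheme = DiagnosticScheme(
        reactions={
            "MT_F2+R1": ("mule", 326),
            "MT_F2+R2": ("mule", 276),
            "WT_F1+R1": ("wt", 327),
        }
    )
    assert call_genotype(bands, scheme) == expected


def test_diagnostic_recovers_archetypes_over_random_embeddings():
    """The designed scheme recovers insertion presence for insertion-bearing
    vs insertion-free clones across random locus realisations."""
    for seed in range(25):
        carrier = build_locus(LocusConfig(archetype="62H2", seed=seed))
        free = build_locus(LocusConfig(archetype="1X", seed=seed))
        scheme = design_diagnostic(carrier)
        call_c, bands_c = run_diagnostic(
            {h.name: carrier.hap_genome(i) for i, h in enumerate(carrier.haplotypes)},
            scheme,
        )
        call_f, _ = run_diagnostic(
            {h.name: free.hap_genome(i) for i, h in enumerate(free.haplotypes)},
            scheme,
        )
        assert call_c == "present" and call_f == "absent"
        assert sorted(bands_from_amplicons([])) == []
        assert bands_c["MT_F2+R1"] == [326]


def test_empty_inputs_rejected():
    with pytest.raises(ValueError):
        amplify({}, [])
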