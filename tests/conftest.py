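import numpy as np
import pytest

from intmark import ChromLayout, PeakSet, SiteSet
from intmark import synthetic as syn
from intmark.controls import generate_matched_controls


@pytest.fixture
def toy_layout():
    return ChromLayout(("chr1", "chr2"), np.array([1000, 500]))


def make_peaks(layout, label, triples):
    """Peaks from (chrom_id, start, end[, summit[, amp]]) tuples."""
    cids, start, end, summit, amp = [], [], [], [], []
    for t in triples:
        cids.append(t[0])
        start.append(t[1])
        end.append(t[2])
        summit.append(t[3] if len(t) > 3 else (t[1] + t[2]) // 2)
        amp.append(t[4] if len(t) > 4 else 1.0)
    return PeakSet(label, layout, np.array(cids), np.array(start), np.array(end),
                   np.array(summit), np.array(amp))


def make_sites(layout, pairs, label="sites"):
    cids = np.array([p[0] for p in pairs], dtype=np.int64)
    pos = np.array([p[1] for p in pairs], dtype=np.int64)
    return SiteSet(label, layout, cids, pos)


@pytest.fixture(scope="session")
def planted_bundle():
    """The standard synthetic study: 2x5 Mb genome, 1000 peaks, V=500 sites
    planted at fraction q=0.7 with 500 bp offsets, 10 matched controls per
    site.  Session-scoped: several tests reuse it read-only."""
    layout, index = syn.simulate_genome(seed=101)
    marker = syn.simulate_peakset(layout, 1000, 400, seed=101, label="H3K4me3-like")
    sites, planted = syn.simulate_integrations(layout, marker, 500, 0.7, 500,
                                               seed=101)
    controls = generate_matched_controls(sites, index, 10, seed=202)
    return {"layout": layout, "index": index, "marker": marker,
            "sites": sites, "planted": planted, "controls": controls}
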