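"""EMU decomposition and steady-state MID simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emuflux as ef
from emuflux.emu import EMU, convolve_mids, full_emu

TOY_CASES = {
    "chain": ({"HK": 1.0, "PPP": 1.0},
              ef.TracerSpec.uniform("GLC", 6, purity=0.95, unlabeled_fraction=0.2)),
    "serine_split": ({"SSP": 0.2, "SER_UPT": 0.8, "SHMT": 1.0},
                     ef.TracerSpec("3PG", (1.0, 1.0, 1.0), purity=0.9,
                                   unlabeled_fraction=0.1)),
    "diamond": ({"R1": 0.3, "R2": 0.7, "R3": 0.3, "R4": 0.7},
                ef.TracerSpec("A", (1.0, 0.5, 0.0, 0.8))),
    "tca_cycle": ({"PDH": 2.0, "PC": 0.5, "CS": 2.0, "TCA2": 2.0, "OUT": 0.5},
                  ef.TracerSpec.uniform("PYR", 3, purity=0.99)),
    "transketolase": ({"TK": 1.0, "S1": 1.0, "G1": 1.0},
                      ef.TracerSpec("X5P", (1.0,) * 5, purity=0.9)),
}


def _simulated(net, fluxes, tracer, targets):
    system = ef.emu_decompose(net, targets)
    return {e.metabolite: m for e, m in ef.simulate_mids(system, fluxes, tracer).items()}


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ([1, 0], [1, 0], [1, 0, 0]),
    ([0, 1], [0, 1], [0, 0, 1]),
    ([0.5, 0.5], [0.5, 0.5], [0.25, 0.5, 0.25]),
])
def test_convolve_examples(a, b, expected):
    assert np.allclose(convolve_mids(a, b), expected)


def test_convolve_rejects_unnormalized():
    with pytest.raises(ValueError, match="sum"):
        convolve_mids([0.5, 0.4], [1.0, 0.0])


@st.composite
def mids(draw):
    n = draw(st.integers(1, 5))
    raw = draw(st.lists(st.floats(0.001, 1.0), min_size=n + 1, max_size=n + 1))
    arr = np.asarray(raw)
    return arr / arr.sum()


@settings(derandomize=True, max_examples=50)
@given(mids(), mids(), mids())
def test_convolution_algebra(a, b, c):
    """Commutative, associative; the m+0 point mass is the identity."""
    ab = convolve_mids(a, b)
    assert np.allclose(ab, convolve_mids(b, a))
    assert np.allclose(convolve_mids(ab, c), convolve_mids(a, convolve_mids(b, c)),
                       atol=1e-12)
    e0 = np.zeros(3); e0[0] = 1.0
    assert np.allclose(convolve_mids(a, e0)[: len(a)], a)
    assert abs(ab.sum() - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def test_decompose_simple_transfer():
    net = ef.parse_network_text("SOURCE A 2\nSINK B\nR1: 1 A (ab) -> 1 B (ab)")
    system = ef.emu_decompose(net, [EMU("B", (1, 2))])
    assert system.n_unknowns == 1
    (er,) = system.reactions_by_product[EMU("B", (1, 2))]
    assert er.sources == (EMU("A", (1, 2)),)


def test_decompose_glycine_traces_serine_carbons():
    net = ef.load_toy_network("serine_split")
    system = ef.emu_decompose(net, [EMU("GLY", (1, 2))])
    (er,) = system.reactions_by_product[EMU("GLY", (1, 2))]
    assert er.sources == (EMU("SER", (1, 2)),)


def test_decompose_cycle_contains_convolution_node():
    net = ef.load_toy_network("tca_cycle")
    system = ef.emu_decompose(net, ["AKG"])
    assert any(
        len(er.sources) >= 2
        for ers in system.reactions_by_product.values() for er in ers
    )


def test_decompose_unreachable_target_names_the_emu():
    # A is balanced (not declared a source) but nothing produces it
    net = ef.parse_network_text("SINK B\nR1: 1 A (ab) -> 1 B (ab)")
    with pytest.raises(ValueError, match=r"A\[1,2\].*unreachable|unreachable.*A"):
        ef.emu_decompose(net, ["A"])


def test_emu_position_validation(network):
    with pytest.raises(ValueError, match="positions"):
        ef.emu_decompose(network, [EMU("SER", (2, 1))])
    with pytest.raises(ValueError, match="outside"):
        ef.emu_decompose(network, [EMU("SER", (1, 4))])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def test_unlabeled_tracer_gives_unlabeled_mids(network, control):
    sim = _simulated(network, control.fluxes, None, ["SER", "IMP", "OAA"])
    for mid in sim.values():
        assert np.allclose(mid, np.eye(len(mid))[0], atol=1e-12)


def test_pure_tracer_single_path_r5p(network, control, tracer):
    """With pure [U-13C] substrate the oxidative-PPP product is fully m+5."""
    sim = _simulated(network, control.fluxes, tracer, ["R5P"])
    assert np.allclose(sim["R5P"], [0, 0, 0, 0, 0, 1], atol=1e-12)


def test_two_input_pool_mixes_linearly():
    """Serine m+3 = (de novo share) * (3PG m+3) when uptake is unlabeled."""
    net = ef.load_toy_network("serine_split")
    p = 0.8
    tr = ef.TracerSpec.uniform("3PG", 3, unlabeled_fraction=1 - p)
    for f in (0.1, 0.5, 0.9):
        sim = _simulated(net, {"SSP": f, "SER_UPT": 1 - f, "SHMT": 1.0}, tr, ["SER"])
        assert sim["SER"][3] == pytest.approx(f * p, abs=1e-12)


def test_flux_scale_invariance(network, control, tracer):
    targets = ["IMP", "UMP", "OAA"]
    a = _simulated(network, control.fluxes, tracer, targets)
    scaled = {k: 7.3 * v for k, v in control.fluxes.values.items()}
    b = _simulated(network, scaled, tracer, targets)
    for m in targets:
        assert np.allclose(a[m], b[m], atol=1e-12)


def test_simulated_mids_normalized(network, control, tracer):
    sim = _simulated(network, control.fluxes, tracer, network.balanced_pools())
    for mid in sim.values():
        assert abs(mid.sum() - 1.0) < 1e-9
        assert (mid >= -1e-12).all()


def test_negative_flux_rejected(network, control, tracer):
    bad = dict(control.fluxes.values)
    bad["PPP"] = -0.1
    system = ef.emu_decompose(network, ["R5P"])
    with pytest.raises(ValueError, match="negative"):
        ef.simulate_mids(system, bad, tracer)


def test_zero_production_rejected():
    net = ef.load_toy_network("serine_split")
    system = ef.emu_decompose(net, ["SER"])
    with pytest.raises(ValueError, match="zero total production"):
        ef.simulate_mids(system, {"SSP": 0.0, "SER_UPT": 0.0, "SHMT": 1.0},
                         ef.TracerSpec.uniform("3PG", 3))


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("toy", sorted(TOY_CASES))
def test_emu_matches_bruteforce_on_toys(toy):
    net = ef.load_toy_network(toy)
    fluxes, tr = TOY_CASES[toy]
    targets = net.balanced_pools()
    bf = ef.enumerate_isotopomers_bruteforce(net, fluxes, tr, targets)
    emu = _simulated(net, fluxes, tr, targets)
    for m in targets:
        assert np.abs(emu[m] - bf[m]).max() < 1e-10


def test_bruteforce_identity_network_returns_tracer_mid():
    net = ef.parse_network_text("SOURCE A 3\nSINK B\nR1: 1 A (abc) -> 1 B (abc)")
    tr = ef.TracerSpec("A", (0.9, 0.5, 0.1))
    bf = ef.enumerate_isotopomers_bruteforce(net, {"R1": 1.0}, tr, ["B"])
    assert np.allclose(bf["B"], tr.emu_mid((1, 2, 3)), atol=1e-12)


def test_bruteforce_rejects_large_state_space():
    net = ef.parse_network_text(
        "SOURCE A 13\nSINK B\nR1: 1 A (abcdefghijklm) -> 1 B (abcdefghijklm)"
    )
    with pytest.raises(ValueError, match="EMU"):
        ef.enumerate_isotopomers_bruteforce(net, {"R1": 1.0}, None, ["B"])
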