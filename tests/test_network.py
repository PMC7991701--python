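"""Network domain model: fixture I/O, validation, interventions."""

import copy

import pytest

from carotidsim.network import (
    COW_SEGMENT_NAMES,
    ArterialNetwork,
    ClampSpec,
    Junction,
    NetworkValidationError,
    StenosisSpec,
    apply_clamp,
    apply_stenosis,
    load_network,
    network_from_dict,
    network_to_dict,
    write_network,
)
from carotidsim.patient import default_fixture_path

from .conftest import make_segment, make_terminal


def test_shipped_fixture_contains_complete_circle_of_willis():
    net = load_network(default_fixture_path())
    names = {s.name for s in net.segments.values()}
    assert COW_SEGMENT_NAMES <= names
    assert len(net.segments) >= 50  # systemic tree plus CoW


def test_fixture_round_trip_is_lossless(tmp_path, single_vessel_net):
    net = load_network(default_fixture_path())
    net.stenoses.append(StenosisSpec("L_ICA", 10.0, 10.0, 0.7))
    net.clamps.append(ClampSpec("R_ICA", 10.0))
    p = tmp_path / "net.json"
    write_network(net, p)
    again = load_network(p)
    assert network_to_dict(again) == network_to_dict(net)


@pytest.mark.parametrize(
    "mutate, match",
    [
        (lambda d: d["segments"][0].update(length_cm=-1), "length"),
        (lambda d: d["segments"][0].update(r_prox_cm=0.0), "radii"),
        (lambda d: d["segments"].append(dict(d["segments"][0])), "duplicate"),
        (lambda d: d["junctions"][0]["attached"].__setitem__(0, ["nosuch", "distal"]),
         "unknown segment"),
        (lambda d: d.update(inflow_segment="nosuch"), "unknown segment"),
    ],
)
def test_validation_names_offending_record(mutate, match):
    doc = network_to_dict(load_network(default_fixture_path()))
    mutate(doc)
    with pytest.raises(NetworkValidationError, match=match):
        network_from_dict(copy.deepcopy(doc))


def test_segment_attached_twice_to_same_junction_rejected():
    root = make_segment("root", length=5.0)
    seg = make_segment("a", length=5.0)
    loop = Junction(
        "j", [("root", "distal"), ("a", "proximal"), ("a", "distal")]
    )
    net = ArterialNetwork(
        segments={"root": root, "a": seg}, junctions=[loop], terminals={},
        inflow_segment="root",
    )
    with pytest.raises(NetworkValidationError, match="both ends"):
        from carotidsim.network import validate_network

        validate_network(net)


def test_dangling_end_rejected():
    from carotidsim.network import validate_network

    seg = make_segment("a")
    net = ArterialNetwork(segments={"a": seg}, junctions=[], terminals={},
                          inflow_segment="a")
    with pytest.raises(NetworkValidationError, match="dangling"):
        validate_network(net)


def test_cerebral_network_missing_communicating_artery_rejected():
    from carotidsim.network import validate_network

    net = load_network(default_fixture_path())
    acom = net.segment_by_name("Acom")
    del net.segments[acom.id]
    net.junctions = [
        Junction(j.node_id, [a for a in j.attached if a[0] != acom.id])
        for j in net.junctions
    ]
    with pytest.raises(NetworkValidationError, match="Acom"):
        validate_network(net)


class TestInterventions:
    def test_apply_stenosis_is_pure(self, single_vessel_net):
        before = network_to_dict(single_vessel_net)
        out = apply_stenosis(single_vessel_net, StenosisSpec("ao", 10.0, 10.0, 0.7))
        assert network_to_dict(single_vessel_net) == before
        assert len(out.stenoses) == 1 and out.stenoses[0].ratio == 0.7

    def test_apply_clamp_is_pure(self, single_vessel_net):
        before = network_to_dict(single_vessel_net)
        out = apply_clamp(single_vessel_net, ClampSpec("ao", 20.0))
        assert network_to_dict(single_vessel_net) == before
        assert len(out.clamps) == 1

    def test_stenosis_outside_segment_rejected(self, single_vessel_net):
        # segment is 10 cm = 100 mm long
        with pytest.raises(NetworkValidationError, match="beyond"):
            apply_stenosis(single_vessel_net, StenosisSpec("ao", 95.0, 10.0, 0.5))

    def test_clamp_outside_segment_rejected(self, single_vessel_net):
        with pytest.raises(NetworkValidationError, match="outside"):
            apply_clamp(single_vessel_net, ClampSpec("ao", 150.0))

    def test_bad_ratio_rejected(self, single_vessel_net):
        with pytest.raises(NetworkValidationError, match="ratio"):
            apply_stenosis(single_vessel_net, StenosisSpec("ao", 10.0, 10.0, 1.5))
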