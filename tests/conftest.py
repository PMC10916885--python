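import pytest

from shadowcue.scene import (
    CameraWalk,
    RoomParams,
    generate_room,
    light_schedule,
    render_snapshot,
)


@pytest.fixture(scope="session")
def room():
    return generate_room(1)


@pytest.fixture(scope="session")
def empty_room_params():
    return RoomParams(n_specs=0, n_instantiated=0)


@pytest.fixture(scope="session")
def empty_room(empty_room_params):
    return generate_room(1, empty_room_params)


@pytest.fixture(scope="session")
def pose(room):
    return CameraWalk(room, 2).pose_at(10.0)


@pytest.fixture(scope="session")
def snapshot(room, pose):
    return render_snapshot(room, pose, light_schedule("reliable", 1, 3))
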