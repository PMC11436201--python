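"""Snake-path scan ordering and four-corner well-center calibration.

The imaging rig visits the 48 wells of a 6x8 plate in a boustrophedon
path and is calibrated by centering a target on the four corner wells;
every other well center is bilinearly interpolated between those corners.
"""

from ovicount import CornerCalibration, PlateGrid, interpolate_well_centers, snake_path

grid = PlateGrid()  # 6 rows x 8 cols = 48 wells
path = snake_path(grid)
print("first row of the scan path: ", " ".join(a.label for a in path[:8]))
print("second row (reversed):      ", " ".join(a.label for a in path[8:16]))

# corner well centers as measured on the rig, in mm
calib = CornerCalibration(
    top_left=(12.0, 10.5),
    top_right=(103.2, 11.1),
    bottom_left=(11.4, 75.9),
    bottom_right=(102.8, 76.6),
)
centers = interpolate_well_centers(calib, grid)
for label in ("A1", "C4", "F8"):
    addr = next(a for a in path if a.label == label)
    x, y = centers[addr]
    print(f"well {label}: interpolated center ({x:.2f}, {y:.2f}) mm")

# A1 reproduces the top-left calibration point exactly; interior wells are
# blends of all four corners, so a slightly skewed plate is handled.
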