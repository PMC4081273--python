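"""Detect lines and circles with Hough transforms.

Rasterizes a column, a row and a circle into a binary image, then reads
their parameters back from the straight-line and circular Hough
accumulators.
"""

import numpy as np

from microimage import draw_circle_perimeter, hough_circle, hough_line, paint

edges = np.zeros((100, 100), bool)
edges[:, 20] = True          # vertical line x = 20
edges[70, :] = True          # horizontal line y = 70
paint(edges, draw_circle_perimeter(40, 60, 18), True)

lines = hough_line(edges)
print("line peaks (votes, theta_rad, rho):")
for count, theta, rho in lines.peaks[:2]:
    print(f"  {count:4d}  {theta:+.3f}  {rho:+.0f}")
# theta 0 / rho 20 is the column; theta -pi/2 / rho -70 the row

circles = hough_circle(edges, np.arange(12, 25))
count, row, col, radius = circles.peaks[0]
print(f"circle peak: center ({row}, {col}), radius {radius}, {count} votes")
# every perimeter pixel votes for the true center, so the drawn circle
# dominates all other radii
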