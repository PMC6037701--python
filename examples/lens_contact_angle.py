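"""Contact angle of an inter-leaflet lens from an AFM line profile.

Bright mobile inclusions trapped between the two leaflets of a membrane
patch are modelled as two back-to-back spherical caps.  From the measured
in-plane radius w and half-thickness h, the contact angle follows from
sin(theta) = 2hw / (h^2 + w^2).
"""

from anxmorph.lens import cap_radius_of_curvature, contact_angle

NM, UM = 1e-9, 1e-6

h = 275 * NM  # half-thickness from the AFM height profile
w = 2 * UM    # in-plane lens radius

theta = contact_angle(h, w)
R = cap_radius_of_curvature(h, w)
print(f"contact angle theta = {theta:.1f} deg")
print(f"cap radius of curvature R = {R / UM:.2f} um")
# A shallow ~16 degree angle, comparable to hydrophobic (e.g. triolein)
# lenses in lipid bilayers; R sin(theta) returns the lens radius w.
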