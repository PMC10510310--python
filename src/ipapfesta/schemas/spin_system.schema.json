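{
  "$defs": {
    "ProtonSite": {
      "description": "One proton site of a simulated spin system.\n\nParameters\n----------\nlabel : str\n    Site name, e.g. ``\"H4a\"`` (``a`` axial, ``b`` equatorial).\nshift : float\n    Chemical shift in Hz relative to the carrier.\namplitude : float\n    Multiplet integral in arbitrary units; must be positive.\njhh : list of (str, float)\n    Homonuclear coupling partners as ``(partner_label, J_HH in Hz)``.\njhf : float\n    Signed heteronuclear \u00b9H\u2013\u00b9\u2079F coupling in Hz.\nlinewidth : float\n    Lorentzian full width at half maximum in Hz; must be positive.",
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "shift": {
          "title": "Shift",
          "type": "number"
        },
        "amplitude": {
          "default": 1.0,
          "title": "Amplitude",
          "type": "number"
        },
        "jhh": {
          "items": {
            "maxItems": 2,
            "minItems": 2,
            "prefixItems": [
              {
                "type": "string"
              },
              {
                "type": "number"
              }
            ],
            "type": "array"
          },
          "title": "Jhh",
          "type": "array"
        },
        "jhf": {
          "default": 0.0,
          "title": "Jhf",
          "type": "number"
        },
        "linewidth": {
          "default": 1.0,
          "title": "Linewidth",
          "type": "number"
        }
      },
      "required": [
        "label",
        "shift"
      ],
      "title": "ProtonSite",
      "type": "object"
    }
  },
  "description": "A \u00b9\u2079F-coupled spin system selected by the fluorine-edited experiment.\n\nOnly protons listed in ``members`` belong to the spin system of\n``fluorine_label`` and survive the spectral editing; everything else is\nassumed perfectly suppressed.  ``relaxation_attenuation`` (\u03c1) is the\nuniform factor by which AP amplitudes are attenuated relative to IP,\nmodelling the faster transverse relaxation of anti-phase coherences.",
  "properties": {
    "fluorine_label": {
      "default": "F",
      "title": "Fluorine Label",
      "type": "string"
    },
    "protons": {
      "items": {
        "$ref": "#/$defs/ProtonSite"
      },
      "title": "Protons",
      "type": "array"
    },
    "members": {
      "items": {
        "type": "string"
      },
      "title": "Members",
      "type": "array"
    },
    "relaxation_attenuation": {
      "default": 1.0,
      "title": "Relaxation Attenuation",
      "type": "number"
    }
  },
  "required": [
    "protons"
  ],
  "title": "SpinSystemSpec",
  "type": "object"
}
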