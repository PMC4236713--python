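34.7964805C00001+40.1701382C00002+0.00780937C00003+0.00780937C00006+0.00780937C00010+0.00780937C00016+0.00780937C00018+0.00780937C00019+0.25601316C00025+0.00780937C00034+0.59580299C00037+0.00780937C00038+0.50005823C00041+0.20910125C00044+0.33354560C00047+0.23467873C00049+0.00780931C00059+0.28827498C00062+0.12987656C00063+0.25601316C00064+0.20970184C00716+0.00780937C00070+0.14934101C00073+0.14026667C00075+0.00780937C00076+0.05515731C00078+0.18056213C00079+0.13425080C00082+0.08898018C00097+0.00780937C00698+0.43865670C00123+0.01174687C00131+0.09262265C00135+0.21542571C00148+0.23467873C00152+0.00780937C00175+0.41159840C00183+0.24664683C00188+0.00780937C00238+0.00780937C00255+0.01174687C00286+0.00780937C00305+0.28255111C00407+0.01174687C00458+0.01174687C00459+0.09247649C04574+0.00780937C14818+0.00780937C14819+0.00780937C00229-->40.0000000C00008+39.9921906C00009+0.60239528C00013+40.0000000C00080+0.00780937C03688
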