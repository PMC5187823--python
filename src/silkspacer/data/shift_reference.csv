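residue,atom,class,low_ppm,high_ppm
G,CA,observed,43.2,43.2
G,CA,alpha,46.0,46.0
G,CA,beta,43.2,44.3
G,CA,coil,43.4,43.4
G,CA,helix31,41.4,42.5
G,CO,observed,169.7,169.7
G,CO,alpha,174.9,174.9
G,CO,beta,168.4,169.7
G,CO,coil,173.2,173.2
A,CA,observed,49.3,49.3
A,CA,observed,50.3,50.3
A,CA,alpha,52.3,52.8
A,CA,beta,48.2,49.3
A,CA,coil,50.8,50.8
A,CA,helix31,48.9,48.9
A,CB,observed,17.4,17.4
A,CB,observed,20.9,20.9
A,CB,alpha,14.8,16.0
A,CB,beta,19.9,20.7
A,CB,coil,17.4,17.4
A,CB,helix31,17.4,17.4
A,CO,observed,172.8,172.8
A,CO,observed,174.5,174.5
A,CO,alpha,176.2,176.8
A,CO,beta,171.6,172.2
A,CO,coil,176.1,176.1
A,CO,helix31,174.6,174.6
Q,CO,observed,172.6,172.6
Q,CO,alpha,175.4,175.9
Q,CO,beta,171.9,172.2
Q,CO,coil,174.3,174.3
Q,CA,observed,52.7,52.7
Q,CA,alpha,56.4,57.0
Q,CA,beta,51.0,51.4
Q,CA,coil,54.0,54.0
Q,CB,observed,25.8,25.8
Q,CB,alpha,25.6,26.3
Q,CB,beta,29.0,29.9
Q,CB,coil,27.7,27.7
Q,CG,observed,30.6,30.6
Q,CG,alpha,29.7,29.8
Q,CG,beta,29.7,29.9
Q,CG,coil,32.0,32.0
Q,CD,observed,176.6,176.6
Q,CD,coil,178.8,178.8
Y,CO,observed,172.7,172.7
Y,CO,alpha,176.7,176.7
Y,CO,beta,169.7,169.7
Y,CO,coil,174.2,174.2
Y,CA,observed,55.1,55.1
Y,CA,alpha,54.8,58.6
Y,CA,beta,52.1,52.1
Y,CA,coil,56.2,56.2
Y,CB,observed,37.7,37.7
Y,CB,alpha,36.1,36.1
Y,CB,beta,39.3,39.3
Y,CB,coil,37.1,37.1
Y,CG,observed,128.6,128.6
Y,CG,alpha,129.7,129.7
Y,CG,beta,128.0,128.0
Y,CG,coil,128.9,128.9
Y,CD,observed,130.9,130.9
Y,CD,alpha,129.7,129.7
Y,CD,beta,128.0,128.0
Y,CD,coil,131.6,131.6
Y,CE,observed,116.1,116.1
Y,CE,alpha,116.1,116.1
Y,CE,beta,115.0,115.0
Y,CE,coil,116.5,116.5
Y,CZ,observed,156.2,156.2
Y,CZ,alpha,154.2,154.2
Y,CZ,beta,155.2,155.2
Y,CZ,coil,155.6,155.6
L,CO,observed,176.0,176.0
L,CO,alpha,175.7,175.7
L,CO,beta,170.5,171.3
L,CO,coil,175.9,175.9
L,CA,observed,53.8,53.8
L,CA,alpha,55.7,55.7
L,CA,beta,50.5,51.2
L,CA,coil,53.4,53.4
L,CB,observed,41.6,41.6
L,CB,alpha,39.5,39.5
L,CB,beta,43.3,43.3
L,CB,coil,40.7,40.7
L,CG,observed,24.0,24.0
L,CG,coil,25.2,25.2
L,CD,observed,23.3,23.3
L,CD,alpha,24.4,24.4
L,CD,beta,24.9,24.9
L,CD,coil,24.3,24.3
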