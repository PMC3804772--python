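compound_id,cell_line,ic50_mean,ic50_sd
5a,CEM,8.9,0.6
5a,HeLa,20.9,1.8
5a,A549,41.6,2.1
5a,MCF-7,33.6,1.3
6a,CEM,8.3,0.4
6a,HeLa,19.4,1.4
6a,A549,37.7,1.8
6a,MCF-7,31.2,1.5
6b,CEM,9.0,0.4
6b,HeLa,21.2,2.1
6b,A549,42.4,2.3
6b,MCF-7,34.1,1.6
6c,CEM,10.0,0.8
6c,HeLa,23.7,1.5
6c,A549,49.0,2.5
6c,MCF-7,38.2,2.5
6d,CEM,7.7,0.3
6d,HeLa,17.9,0.9
6d,A549,33.5,1.7
6d,MCF-7,28.7,0.8
6e,CEM,7.5,0.6
6e,HeLa,17.3,0.7
6e,A549,32.1,1.6
6e,MCF-7,27.8,1.3
6f,CEM,6.7,0.3
6f,HeLa,15.3,0.5
6f,A549,26.9,1.4
6f,MCF-7,24.5,0.8
6g,CEM,11.9,0.8
6g,HeLa,28.3,2.1
6g,A549,61.3,3.1
6g,MCF-7,45.8,2.2
6h,CEM,6.9,0.5
6h,HeLa,15.8,0.5
6h,A549,28.0,1.5
6h,MCF-7,25.3,1.2
6i,CEM,9.5,0.7
6i,HeLa,22.3,1.2
6i,A549,45.4,2.5
6i,MCF-7,36.0,1.9
6j,CEM,13.6,1.3
6j,HeLa,32.4,2.4
6j,A549,72.3,3.5
6j,MCF-7,52.6,3.8
Nos,CEM,14.5,2.5
Nos,HeLa,24.0,2.9
Nos,A549,72.9,4.6
Nos,MCF-7,42.3,2.7
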