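compound,AutoDockTools,LeDock,Qvina,Smina,Vina,PLANTS,rDock
194143-57-2,-13.82,-5.45,-8.2,-8.37179,-8.26,-79.8596,-14.9023
205813-99-6,-13.18,-6.09,-8.5,-8.70485,-8.599,-90.4657,-26.2504
207305-65-5,-10.71,-4.61,-7.6,-7.59515,-7.814,-48.0241,-8.92162
223130-61-8,-11.19,-7.53,-9.4,-9.71733,-9.455,-73.2084,-33.6306
251343-62-1,-13.12,-4.88,-7.6,-7.92827,-7.54,-74.1601,-14.7578
CMNPD10652,-9.21,-4.65,-7.2,-7.53275,-7.067,-79.239,-11.9891
CMNPD11585,-12.43,-7.35,-10.6,-10.6076,-10.541,-83.8021,-36.2474
CMNPD12908,-9.11,-3.99,-6,-6.43511,-5.994,-20.1983,-37.0736
CMNPD1346,-10.67,-5.93,-8.8,-9.50728,-8.622,-85.0765,-23.3839
CMNPD13472,-12.45,-5.83,-9.3,-9.32971,-9.708,-67.0398,-35.665
CMNPD14214,-9.36,-4.96,-9,-9.01676,-9.228,-60.5698,-10.614
CMNPD14217,-12.39,-5.61,-10,-10.2387,-9.929,-85.4462,-34.8739
CMNPD2018,-11.63,-4.12,-7.2,-7.54516,-7.155,-68.0614,-8.30005
CMNPD2744,-10.83,-7.32,-8.9,-9.50247,-9.029,-93.0371,-21.8022
CMNPD3195,-12.58,-3.84,-7,-7.56716,-6.801,-71.031,-11.6868
CMNPD4645,-11.32,-5.98,-7.6,-7.99042,-7.673,-90.7608,-21.0265
CMNPD4920,-12.14,-5.71,-8.4,-8.58632,-8.384,-83.9795,-16.0704
CMNPD5678,-11.66,-5.06,-8.7,-9.20217,-8.378,-75.2528,-11.6789
CMNPD5679,-11.7,-4.07,-5.5,-5.90156,-5.392,-76.619,-1.19659
CMNPD5682,-11.83,-4.51,-6.9,-7.06105,-6.952,-71.4684,-13.2668
CMNPD646,-10.78,-4.99,-6.8,-6.97034,-6.773,-73.5001,-11.1624
CMNPD7036,-12.42,-4.33,-7.6,-8.04135,-7.646,-80.1545,-45.955
CMNPD7986,-15.4,-8.03,-9.1,-9.40776,-9.364,-128.572,-48.8013
CMNPD8752,-12.11,-5.33,-7.7,-7.83148,-7.881,-78.9698,-10.1984
CMNPD9390,-9.11,-4.57,-7.6,-7.56806,-7.593,-49.3505,-9.30684
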